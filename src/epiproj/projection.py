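"""Local-Z projection around the reference surface.

For every (X, Y) position the height-map gives the Z of the layer of
interest; intensity is collected from the slices
``z* + offset - delta_z … z* + offset + delta_z`` (clipped to the stack)
and reduced by max or mean.  A per-channel ``offset`` lets e.g. a
nuclear channel be sampled a few slices below the junctional surface.

:func:`project_stack` is the two-pass driver: pass one extracts the
height-map from the designated channel, pass two projects every
channel.  Each pass touches each plane at most once, so with a streamed
stack every plane is read from disk at most twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .heightmap import HeightMapParams, extract_height_map
from .stack import VolumeStack

__all__ = ["ChannelProjectionParams", "Projection", "project_channel", "project_stack", "mip"]


@dataclass
class ChannelProjectionParams:
    """Accumulation settings for one channel.

    offset: signed shift (slices) relative to the reference surface.
    delta_z: half-range of accumulated slices (0 reads one slice).
    mode: 'max' or 'mean' over the accumulated slices.
    """

    offset: int = 0
    delta_z: int = 0
    mode: str = "max"

    def __post_init__(self) -> None:
        if self.delta_z < 0:
            raise InvalidParameterError(f"delta_z must be >= 0, got {self.delta_z}")
        if self.mode not in ("max", "mean"):
            raise InvalidParameterError(f"mode must be 'max' or 'mean', got {self.mode!r}")


@dataclass
class Projection:
    """Bundle of the two projection outputs: per-channel 2D images and the height-map."""

    images: list[np.ndarray]
    height_map: np.ndarray
    params: list[ChannelProjectionParams] = field(default_factory=list)


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(a, dtype=np.float64) + 0.5).astype(np.int64)


def project_channel(
    stack: VolumeStack,
    channel: int,
    hm: np.ndarray,
    params: ChannelProjectionParams,
) -> np.ndarray:
    """Project one channel around the reference surface.

    Fractional height-map values are rounded half-up to the nearest
    slice.  Accumulation windows are clipped at the stack boundaries and
    mean mode divides by the number of slices actually used.
    """
    hm = np.asarray(hm, dtype=np.float64)
    if hm.shape != stack.shape_yx:
        raise InvalidInputError(
            f"height-map shape {hm.shape} does not match stack planes {stack.shape_yx}"
        )
    if not (0 <= channel < stack.n_channels):
        raise InvalidInputError(f"channel {channel} not in stack ({stack.n_channels} channels)")
    n = stack.n_slices
    zc = _round_half_up(hm) + params.offset
    lo = np.clip(zc - params.delta_z, 0, n - 1)
    hi = np.clip(zc + params.delta_z, 0, n - 1)
    # single pass over the slices actually needed
    out = None
    count = None
    for z in range(int(lo.min()), int(hi.max()) + 1):
        sel = (lo <= z) & (z <= hi)
        if not sel.any():
            continue
        plane = np.asarray(stack.plane(channel, z), dtype=np.float64)
        if params.mode == "max":
            if out is None:
                out = np.full(hm.shape, -np.inf)
            out[sel] = np.maximum(out[sel], plane[sel])
        else:
            if out is None:
                out = np.zeros(hm.shape)
                count = np.zeros(hm.shape, dtype=np.int64)
            out[sel] += plane[sel]
            count[sel] += 1
    if out is None:  # unreachable: lo <= hi always holds after clipping
        raise InvalidInputError("empty accumulation window")
    if params.mode == "mean":
        out = out / count
    return out


def project_stack(
    stack: VolumeStack,
    hm_params: HeightMapParams,
    proj_params: list[ChannelProjectionParams],
) -> Projection:
    """Two-pass projection: extract the height-map, then project every channel."""
    if len(proj_params) != stack.n_channels:
        raise InvalidInputError(
            f"need one ChannelProjectionParams per channel "
            f"({stack.n_channels}), got {len(proj_params)}"
        )
    hm = extract_height_map(stack, hm_params)
    images = [project_channel(stack, c, hm, p) for c, p in enumerate(proj_params)]
    return Projection(images=images, height_map=hm, params=list(proj_params))


def mip(stack: VolumeStack, channel: int) -> np.ndarray:
    """Maximum intensity projection: per-pixel max over all slices.

    The classical baseline; it mixes in signal from every layer of the
    volume, which is exactly the artifact local projection avoids.
    """
    if not (0 <= channel < stack.n_channels):
        raise InvalidInputError(f"channel {channel} not in stack ({stack.n_channels} channels)")
    out = np.asarray(stack.plane(channel, 0), dtype=np.float64).copy()
    for z in range(1, stack.n_slices):
        np.maximum(out, stack.plane(channel, z), out=out)
    return out
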