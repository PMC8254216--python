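"""Reference-surface (height-map) extraction from a 3D stack.

The epithelial layer of interest is assumed single-valued: at most one
surface Z per (X, Y) position.  A 2D filter (sliding-window mean or
standard deviation) is applied to every Z-plane of one designated
channel; for each (X, Y) position the Z-plane with the strongest
response locates the layer.  The resulting height-map is regularized
with a wide median filter and rescaled to the full image extent.

Pipeline order per plane: optional block **binning** (mean aggregation)
→ optional Gaussian pre-smoothing → windowed filter response; then
argmax over Z, median regularization in binned space, bilinear rescale.

All sliding-window filters use symmetric reflective borders
(``scipy.ndimage`` ``mode='reflect'``).  The standard-deviation filter
uses population (N) normalization.  Argmax ties break toward the
smallest z (closest to the objective).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError
from .stack import VolumeStack

__all__ = [
    "HeightMapParams",
    "bin_plane",
    "plane_response",
    "height_map_argmax",
    "regularize_height_map",
    "rescale_height_map",
    "extract_height_map",
]


@dataclass
class HeightMapParams:
    """Parameters of the height-map extraction stage.

    Defaults follow the configuration used for membrane-marker epithelia:
    a 21×21 standard-deviation filter responds strongly to the junctional
    mesh while staying flat on smooth out-of-layer structures.
    """

    filter_kind: str = "std"
    filter_window: int = 21
    binning: int = 2
    presmooth_sigma: float = 0.0
    median_window: int = 21
    target_channel: int = 0

    def __post_init__(self) -> None:
        if self.filter_kind not in ("mean", "std"):
            raise InvalidParameterError(
                f"filter_kind must be 'mean' or 'std', got {self.filter_kind!r}"
            )
        for name in ("filter_window", "median_window"):
            w = getattr(self, name)
            if not (isinstance(w, (int, np.integer)) and w >= 1 and w % 2 == 1):
                raise InvalidParameterError(f"{name} must be an odd integer >= 1, got {w}")
        if not (isinstance(self.binning, (int, np.integer)) and self.binning >= 1):
            raise InvalidParameterError(f"binning must be an integer >= 1, got {self.binning}")
        if self.presmooth_sigma < 0:
            raise InvalidParameterError(
                f"presmooth_sigma must be >= 0, got {self.presmooth_sigma}"
            )


def bin_plane(plane: np.ndarray, b: int) -> np.ndarray:
    """Block-aggregate ``plane`` by ``b``×``b`` mean pooling.

    Output dimensions are ``ceil(h/b) × ceil(w/b)``; partial edge blocks
    are averaged over the pixels they actually contain.  ``b == 1``
    returns the input unchanged.
    """
    if not (isinstance(b, (int, np.integer)) and b >= 1):
        raise InvalidParameterError(f"binning factor must be a positive integer, got {b}")
    plane = np.asarray(plane)
    if b == 1:
        return plane
    h, w = plane.shape
    ri = np.arange(0, h, b)
    ci = np.arange(0, w, b)
    sums = np.add.reduceat(np.add.reduceat(plane.astype(np.float64), ri, axis=0), ci, axis=1)
    rows = np.minimum(ri + b, h) - ri
    cols = np.minimum(ci + b, w) - ci
    return sums / np.outer(rows, cols)


def plane_response(
    plane: np.ndarray,
    kind: str = "std",
    window: int = 21,
    presmooth_sigma: float = 0.0,
) -> np.ndarray:
    """Windowed mean or standard-deviation response of one Z-plane.

    Optional Gaussian pre-smoothing is applied first.  Same output size
    as input; borders use symmetric reflection.
    """
    if window % 2 == 0 or window < 1:
        raise InvalidParameterError(f"filter window must be odd and >= 1, got {window}")
    if kind not in ("mean", "std"):
        raise InvalidParameterError(f"filter kind must be 'mean' or 'std', got {kind!r}")
    p = np.asarray(plane, dtype=np.float64)
    if presmooth_sigma > 0:
        p = ndimage.gaussian_filter(p, presmooth_sigma, mode="reflect")
    m = ndimage.uniform_filter(p, size=window, mode="reflect")
    if kind == "mean":
        return m
    m2 = ndimage.uniform_filter(p * p, size=window, mode="reflect")
    # population variance; tiny negatives from roundoff are clipped
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def height_map_argmax(stack: VolumeStack, params: HeightMapParams) -> np.ndarray:
    """Raw (binned, unregularized) height-map: per-pixel argmax of the response.

    Ties break toward the smallest z.  Shape is the binned plane shape.
    """
    if stack.n_slices < 1:
        raise InvalidInputError("stack has no Z slices")
    if not (0 <= params.target_channel < stack.n_channels):
        raise InvalidInputError(
            f"target_channel {params.target_channel} not in stack "
            f"({stack.n_channels} channels)"
        )
    best_resp = None
    best_z = None
    for z in range(stack.n_slices):
        p = bin_plane(stack.plane(params.target_channel, z), params.binning)
        r = plane_response(p, params.filter_kind, params.filter_window, params.presmooth_sigma)
        if best_resp is None:
            best_resp = r.copy()
            best_z = np.zeros(r.shape, dtype=np.int64)
        else:
            better = r > best_resp  # strict: ties keep the smaller z
            best_resp[better] = r[better]
            best_z[better] = z
    return best_z.astype(np.float64)


def regularize_height_map(hm: np.ndarray, median_window: int) -> np.ndarray:
    """Median-filter the height-map with a wide window (reflective borders)."""
    if median_window % 2 == 0 or median_window < 1:
        raise InvalidParameterError(
            f"median window must be odd and >= 1, got {median_window}"
        )
    return ndimage.median_filter(np.asarray(hm, dtype=np.float64),
                                 size=median_window, mode="reflect")


def rescale_height_map(
    hm: np.ndarray, b: int, target_shape: tuple[int, int]
) -> np.ndarray:
    """Bilinearly upscale a binned height-map to the original image extent.

    Binned pixel ``i`` represents the full-resolution block centred at
    ``i*b + (b-1)/2``, so full-resolution pixel ``x`` samples binned
    coordinate ``(x - (b-1)/2) / b``, clamped at the borders.  With
    ``b == 1`` and matching shape this is the identity.
    """
    hm = np.asarray(hm, dtype=np.float64)
    if not (isinstance(b, (int, np.integer)) and b >= 1):
        raise InvalidParameterError(f"binning factor must be a positive integer, got {b}")
    if b == 1:
        if tuple(target_shape) == hm.shape:
            return hm.copy()
        if target_shape[0] < hm.shape[0] or target_shape[1] < hm.shape[1]:
            raise InvalidParameterError(
                f"cannot rescale {hm.shape} down to {tuple(target_shape)} with b=1"
            )
    ys = (np.arange(target_shape[0]) - (b - 1) / 2.0) / b
    xs = (np.arange(target_shape[1]) - (b - 1) / 2.0) / b
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(hm, [yy, xx], order=1, mode="nearest")


def extract_height_map(stack: VolumeStack, params: HeightMapParams) -> np.ndarray:
    """Full extraction: binned argmax → median regularization → rescale.

    Returns a finite, real-valued ``(y, x)`` map of Z positions in slice
    units, at the full stack extent, with every value in
    ``[0, n_slices - 1]``.
    """
    raw = height_map_argmax(stack, params)
    reg = regularize_height_map(raw, params.median_window)
    return rescale_height_map(reg, params.binning, stack.shape_yx)
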