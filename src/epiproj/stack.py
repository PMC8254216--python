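"""Calibrated multi-channel 3D intensity stacks.

A :class:`VolumeStack` is a stack of Z-planes per channel with voxel
calibration (``dx``, ``dy`` pixel size and ``dz`` slice spacing, in μm).
The only access pattern the rest of the package requires is random access
to a single ``(channel, z)`` plane, which lets large stacks be streamed
from disk one plane at a time instead of being held in memory.

Two concrete implementations are provided:

* :class:`ArrayStack` — an eager, in-memory ``(C, Z, Y, X)`` array.
* :class:`StreamedTiffStack` (in :mod:`epiproj.io`) — plane-on-demand
  access to a TIFF file.

:class:`InstrumentedStack` wraps any stack and counts how often each
plane is requested; the projection pipeline guarantees every plane is
read at most twice (once for surface extraction, once for projection),
which makes out-of-core operation practical.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .errors import InvalidInputError

__all__ = ["VolumeStack", "ArrayStack", "InstrumentedStack"]


class VolumeStack:
    """Abstract calibrated stack; subclasses implement :meth:`plane`."""

    n_channels: int
    n_slices: int
    shape_yx: tuple[int, int]
    dx: float
    dy: float
    dz: float

    def plane(self, c: int, z: int) -> np.ndarray:
        """Return the 2D ``(y, x)`` intensity plane for channel ``c``, slice ``z``."""
        raise NotImplementedError

    def _check_indices(self, c: int, z: int) -> None:
        if not (0 <= c < self.n_channels):
            raise InvalidInputError(
                f"channel {c} out of range (stack has {self.n_channels} channels)"
            )
        if not (0 <= z < self.n_slices):
            raise InvalidInputError(
                f"slice {z} out of range (stack has {self.n_slices} slices)"
            )

    def to_array(self) -> np.ndarray:
        """Materialize the full ``(C, Z, Y, X)`` array (loads every plane)."""
        return np.stack(
            [
                np.stack([self.plane(c, z) for z in range(self.n_slices)])
                for c in range(self.n_channels)
            ]
        )


class ArrayStack(VolumeStack):
    """In-memory stack backed by a ``(C, Z, Y, X)`` or ``(Z, Y, X)`` array."""

    def __init__(
        self,
        data: np.ndarray,
        dx: float = 1.0,
        dy: float = 1.0,
        dz: float = 1.0,
    ):
        data = np.asarray(data)
        if data.ndim == 3:
            data = data[None]
        if data.ndim != 4:
            raise InvalidInputError(
                f"stack data must be (Z, Y, X) or (C, Z, Y, X), got shape {data.shape}"
            )
        if data.shape[1] < 1:
            raise InvalidInputError("stack must have at least one Z slice")
        if np.any(data < 0):
            raise InvalidInputError("stack intensities must be non-negative")
        for v, name in ((dx, "dx"), (dy, "dy"), (dz, "dz")):
            if not v > 0:
                raise InvalidInputError(f"calibration {name} must be positive, got {v}")
        self.data = data
        self.n_channels = data.shape[0]
        self.n_slices = data.shape[1]
        self.shape_yx = (data.shape[2], data.shape[3])
        self.dx, self.dy, self.dz = float(dx), float(dy), float(dz)

    def plane(self, c: int, z: int) -> np.ndarray:
        self._check_indices(c, z)
        return self.data[c, z]


class InstrumentedStack(VolumeStack):
    """Wrapper that counts plane accesses of an underlying stack.

    ``read_counts[(c, z)]`` gives the number of times that plane was
    requested; :attr:`max_reads` is the maximum over all planes.
    """

    def __init__(self, inner: VolumeStack):
        self.inner = inner
        self.n_channels = inner.n_channels
        self.n_slices = inner.n_slices
        self.shape_yx = inner.shape_yx
        self.dx, self.dy, self.dz = inner.dx, inner.dy, inner.dz
        self.read_counts: Counter[tuple[int, int]] = Counter()

    def plane(self, c: int, z: int) -> np.ndarray:
        self.read_counts[(c, z)] += 1
        return self.inner.plane(c, z)

    @property
    def max_reads(self) -> int:
        return max(self.read_counts.values(), default=0)
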