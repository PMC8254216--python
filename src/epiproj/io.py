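"""TIFF stack reading/writing, run configuration and output bundles.

Stacks are read with :mod:`tifffile`; multi-page files are interpreted
with ImageJ hyperstack conventions (axis order XYCZT, i.e. channel
varies fastest across pages, then slice, then frame), overridable via
the declared axis order.  Streaming mode keeps the file handle open and
reads one plane at a time with an instrumentable read counter, so the
two-pass projection touches every plane at most twice regardless of
stack size.

Calibration precedence is explicit arguments > TIFF metadata > error:
``dz`` scales every 3D metric downstream, so it is never silently
defaulted unless the caller opts in with ``default_calibration``.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidParameterError, StackIOError
from .heightmap import HeightMapParams
from .projection import ChannelProjectionParams, Projection
from .stack import ArrayStack, VolumeStack

__all__ = ["read_stack", "write_stack", "write_height_map", "read_height_map",
           "write_outputs", "StreamedTiffStack", "RunConfig"]


def _resolve_axes(axes: str, shape: tuple) -> dict[str, int]:
    """Map axis letters to their sizes, defaulting missing axes to 1."""
    sizes = dict(zip(axes.upper(), shape))
    for ax in "TZCYX":
        sizes.setdefault(ax, 1)
    return sizes


def _resolve_calibration(tif, dx, dy, dz, default):
    """Explicit args > ImageJ/TIFF metadata > default (or error)."""
    meta = tif.imagej_metadata or {}
    page = tif.pages[0]
    if dx is None or dy is None:
        try:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            mx = xres[1] / xres[0] if xres[0] else None
            my = yres[1] / yres[0] if yres[0] else None
        except (KeyError, TypeError, ZeroDivisionError):
            mx = my = None
        dx = dx if dx is not None else mx
        dy = dy if dy is not None else my
    if dz is None:
        dz = meta.get("spacing")
    if dx is None or dy is None or dz is None:
        if default is None:
            raise StackIOError(
                "voxel calibration (dx, dy, dz) not given and not found in TIFF "
                "metadata; pass it explicitly (dz scales all 3D measurements)")
        dx = dx if dx is not None else default[0]
        dy = dy if dy is not None else default[1]
        dz = dz if dz is not None else default[2]
    return float(dx), float(dy), float(dz)


class StreamedTiffStack(VolumeStack):
    """Plane-on-demand TIFF stack with a per-plane read counter.

    Pages are assumed in ImageJ hyperstack order (channel fastest, then
    slice, then frame); ``timepoint`` selects one frame.
    """

    def __init__(self, path, n_channels: int, n_slices: int, n_frames: int = 1,
                 timepoint: int = 0, dx: float = 1.0, dy: float = 1.0,
                 dz: float = 1.0):
        self.path = Path(path)
        self._tif = tifffile.TiffFile(self.path)
        self.n_channels = n_channels
        self.n_slices = n_slices
        self.n_frames = n_frames
        self.timepoint = timepoint
        page0 = self._tif.pages[0]
        self.shape_yx = tuple(page0.shape[-2:])
        self.dx, self.dy, self.dz = float(dx), float(dy), float(dz)
        self.read_counts: Counter[tuple[int, int]] = Counter()
        expected = n_channels * n_slices * n_frames
        if len(self._tif.pages) < expected:
            raise StackIOError(
                f"{self.path}: expected {expected} pages "
                f"(C={n_channels} × Z={n_slices} × T={n_frames}), "
                f"found {len(self._tif.pages)}")

    def plane(self, c: int, z: int) -> np.ndarray:
        self._check_indices(c, z)
        self.read_counts[(c, z)] += 1
        idx = (self.timepoint * self.n_slices + z) * self.n_channels + c
        try:
            return self._tif.pages[idx].asarray()
        except Exception as exc:  # corrupt page
            raise StackIOError(f"{self.path}: cannot read plane c={c}, z={z}: {exc}") from exc

    @property
    def max_reads(self) -> int:
        return max(self.read_counts.values(), default=0)

    def close(self) -> None:
        self._tif.close()


def read_stack(path, axis_order: str | None = None, streaming: bool = False,
               timepoint: int = 0, dx: float | None = None,
               dy: float | None = None, dz: float | None = None,
               default_calibration: tuple[float, float, float] | None = None
               ) -> VolumeStack:
    """Read a TIFF stack as a :class:`VolumeStack`.

    ``axis_order`` declares the axes of the stored array (subset of
    TZCYX, e.g. ``"ZYX"`` or ``"TZCYX"``); when None it is taken from
    the file's series metadata.  Eager and streamed modes yield
    identical plane contents; streamed mode additionally exposes
    ``read_counts``.
    """
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"stack file not found: {path}")
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:
        raise StackIOError(f"cannot open {path}: {exc}") from exc
    series = tif.series[0]
    axes = (axis_order or series.axes).upper().replace("S", "C").replace("Q", "Z")
    sizes = _resolve_axes(axes, series.shape)
    dx, dy, dz = _resolve_calibration(tif, dx, dy, dz, default_calibration)
    if streaming:
        return StreamedTiffStack(path, n_channels=sizes["C"], n_slices=sizes["Z"],
                                 n_frames=sizes["T"], timepoint=timepoint,
                                 dx=dx, dy=dy, dz=dz)
    data = series.asarray()
    tif.close()
    # normalize to (T, C, Z, Y, X)
    full = data.reshape([max(sizes[ax], 1) for ax in axes])
    order = [axes.index(ax) for ax in "TCZYX" if ax in axes]
    full = np.transpose(full, order)
    for pos, ax in enumerate("TCZYX"):
        if ax not in axes:
            full = np.expand_dims(full, pos)
    if timepoint >= full.shape[0]:
        raise StackIOError(f"timepoint {timepoint} out of range ({full.shape[0]} frames)")
    return ArrayStack(full[timepoint], dx=dx, dy=dy, dz=dz)


def write_stack(path, data: np.ndarray, dx: float = 1.0, dy: float = 1.0,
                dz: float = 1.0) -> None:
    """Write a ``(C, Z, Y, X)`` or ``(Z, Y, X)`` array as an ImageJ hyperstack TIFF."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 3:
        data = data[None]
    # ImageJ page order: channel fastest -> store as (Z, C, Y, X)
    zcyx = np.transpose(data, (1, 0, 2, 3))
    tifffile.imwrite(
        path, zcyx, imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZCYX"},
    )


def write_height_map(path, hm: np.ndarray) -> None:
    """Write a height-map as a single-plane 32-bit float TIFF (0-based slice index)."""
    tifffile.imwrite(path, np.asarray(hm, dtype=np.float32))


def read_height_map(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"height-map file not found: {path}")
    return np.asarray(tifffile.imread(path), dtype=np.float64)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable description of a full run (projection + deprojection)."""

    heightmap: HeightMapParams = field(default_factory=HeightMapParams)
    channels: list[ChannelProjectionParams] = field(default_factory=list)
    dx: float | None = None
    dy: float | None = None
    dz: float | None = None
    axis_order: str | None = None
    streaming: bool = False
    sigma: str | float = "auto"      # deproj smoothing: 'auto' = median cell diameter
    exclude_border: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
                    else json.load(fh)
        except Exception as exc:
            raise InvalidParameterError(f"cannot parse config {path}: {exc}") from exc
        hm = HeightMapParams(**raw.get("heightmap", {}))
        channels = [ChannelProjectionParams(**c) for c in raw.get("channels", [])]
        keys = {"dx", "dy", "dz", "axis_order", "streaming", "sigma",
                "exclude_border", "seed", "log_level"}
        extra = {k: v for k, v in raw.items() if k in keys}
        return cls(heightmap=hm, channels=channels, **extra)

    def to_file(self, path) -> None:
        from dataclasses import asdict
        raw = {
            "heightmap": asdict(self.heightmap),
            "channels": [asdict(c) for c in self.channels],
            "dx": self.dx, "dy": self.dy, "dz": self.dz,
            "axis_order": self.axis_order, "streaming": self.streaming,
            "sigma": self.sigma, "exclude_border": self.exclude_border,
            "seed": self.seed, "log_level": self.log_level,
        }
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yml", ".yaml"):
                yaml.safe_dump(raw, fh)
            else:
                json.dump(raw, fh, indent=2)


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_CELL_COLUMNS = [
    "label", "area_2d", "area_3d", "perim_2d", "perim_3d",
    "centroid_x", "centroid_y", "centroid_z",
    "normal_x", "normal_y", "normal_z", "slope_theta",
    "euler_alpha", "euler_beta", "euler_gamma",
    "ellipse_a", "ellipse_b", "ellipse_orientation", "orientation_xy",
    "eccentricity", "n_neighbors", "mean_curvature", "gaussian_curvature",
    "err_area", "err_perim", "on_border",
]


def cells_to_frame(cells) -> pd.DataFrame:
    """Per-cell metrics as a DataFrame, one row per cell."""
    if not cells:
        return pd.DataFrame(columns=_CELL_COLUMNS)
    return pd.DataFrame([c.to_row() for c in cells], columns=_CELL_COLUMNS)


def write_outputs(out_dir, projection: Projection | None = None,
                  height_map: np.ndarray | None = None,
                  cells=None, report=None, config: RunConfig | None = None
                  ) -> dict[str, str]:
    """Write every artifact of a run and a checksum manifest.

    Returns the manifest mapping file names to SHA-256 digests; the
    manifest itself is saved as ``manifest.json``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise StackIOError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: list[Path] = []
    if projection is not None:
        p = out_dir / "projection.tif"
        write_stack(p, np.asarray(projection.images)[:, None])
        written.append(p)
        p = out_dir / "heightmap.tif"
        write_height_map(p, projection.height_map)
        written.append(p)
    elif height_map is not None:
        p = out_dir / "heightmap.tif"
        write_height_map(p, height_map)
        written.append(p)
    if cells is not None:
        p = out_dir / "cells.csv"
        cells_to_frame(cells).to_csv(p, index=False)
        written.append(p)
        p = out_dir / "contours.json"
        with open(p, "w") as fh:
            json.dump({str(c.label): c.contour3d.tolist() for c in cells}, fh)
        written.append(p)
    if report is not None:
        p = out_dir / "report.json"
        from dataclasses import asdict, is_dataclass
        with open(p, "w") as fh:
            json.dump(asdict(report) if is_dataclass(report) else report, fh, indent=2)
        written.append(p)
    if config is not None:
        p = out_dir / "config.json"
        config.to_file(p)
        written.append(p)
    manifest = {p.name: _sha256(p) for p in written}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
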