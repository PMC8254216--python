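"""Quick-look renderings of per-cell metrics painted onto the label mask."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_cell_maps"]

_DEFAULT_METRICS = ("area_3d", "err_area", "slope_theta", "mean_curvature")


def _paint(mask: np.ndarray, values: dict[int, float]) -> np.ndarray:
    out = np.full(mask.shape, np.nan)
    for lab, val in values.items():
        out[mask == lab] = val
    return out


def save_cell_maps(mask: np.ndarray, cells, out_dir,
                   metrics=_DEFAULT_METRICS, cmap: str = "viridis") -> list[Path]:
    """Save one PNG per metric, each cell filled with its metric value."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric in metrics:
        values = {c.label: c.to_row()[metric] for c in cells}
        img = _paint(np.asarray(mask), values)
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(img, cmap=cmap)
        ax.set_title(metric)
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.8)
        path = out_dir / f"{metric}_map.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
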