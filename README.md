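# epiproj

Local-Z projection of curved epithelial layers and distortion-corrected
3D cell morphometrics.

## The problem

Epithelial monolayers are imaged as 3D confocal or light-sheet stacks in
which the cell layer of interest is a thin, curved manifold `z = f(x, y)`
surrounded by spurious fluorescent structures (auto-fluorescent cuticle
above, bright fat bodies below, in the classic fly-notum configuration).
Two distortions corrupt the standard 2D analysis workflow:

1. **Projection artifacts.** The maximum intensity projection (MIP) takes
   the brightest voxel along each Z column and therefore mixes signal
   from every layer into the 2D image, ruining segmentation.
2. **Foreshortening.** Any 2D measurement underestimates geometry where
   the tissue is tilted: a planar cell whose apical plane makes an angle
   θ with the imaging plane has its projected area scaled by cos θ, so
   the relative error is `e_a = 1 − a2D/a3D = 1 − cos θ` (and this is a
   lower bound for cells with non-planar contours).

`epiproj` addresses both. A **height-map** is extracted from the stack by
applying a 2D filter (sliding-window mean or standard deviation) to every
Z-plane of a reference channel and taking, per (X, Y), the Z of the
strongest response; the map is regularized with a wide median filter and
rescaled if binning was used. The **local projection** then collects
intensity only in a window `z* + offset ± Δz` around the surface, per
channel. Finally, **deprojection** lifts a 2D cell segmentation onto the
smoothed reference surface and measures each cell in 3D: area, perimeter,
fitted apical plane (normal, slope θ, Euler angles), moment-equivalent
ellipse in the apical plane, eccentricity, neighbor count, and the local
mean and Gaussian curvature of the surface (Monge-patch formulas).

The two-pass design reads every image plane at most twice, so stacks far
larger than memory can be projected by streaming planes from disk.

A synthetic-fixture module generates ground-truthed test scenes (flat /
tilted / bump / sphere-cap / cylinder surfaces, Voronoi cell lattices,
cuticle and fat-body layers, PSF blur, noise), so the entire pipeline is
testable without external data.

## Worked example

```python
import numpy as np
from epiproj import (ChannelProjectionParams, HeightMapParams, deproject,
                     extract_height_map, make_epithelium_mask, make_surface,
                     notum_spec, project_channel, render_stack, rmse)

spec = notum_spec(seed=3)                 # 256x256x32 notum-like stack, SNR ~ 3
f, hm_truth = make_surface(spec)
mask, _ = make_epithelium_mask(spec)
stack, ideal = render_stack(spec, (f, hm_truth), mask)

params = HeightMapParams(filter_kind="std", filter_window=21,
                         binning=1, median_window=51)
hm = extract_height_map(stack, params)
print("height-map RMSE [slices]:", rmse(hm, hm_truth))

proj = project_channel(stack, 0, hm, ChannelProjectionParams(0, 1, "max"))
print("projection RMSE:", rmse(proj, ideal))

cells = deproject(mask, hm, spec.dx, spec.dy, spec.dz)
interior = [c for c in cells if not c.on_border]
print("cells:", len(interior),
      "mean e_a:", np.mean([c.err_area for c in interior]))
```

Output:

```
height-map RMSE [slices]: 0.4266280935903167
projection RMSE: 37.62827618776919
cells: 208 mean e_a: 0.0017621417138541885
```

The height-map lands within half a slice of the generating surface
despite the cuticle sheet, the fat bodies and noise at SNR ≈ 3; the
local projection stays much closer to the ideal membrane image than the
MIP of the same stack (RMSE ≈ 64, dominated by cuticle and fat-body
signal); and the mean area distortion on this gently curved surface is
a fraction of a percent, rising with the local slope as `1 − cos θ`.

The same pipeline is scriptable from the shell:

```sh
epi synth --preset notum --seed 3 --out fixture/
epi heightmap --input fixture/stack.tif --filter std --window 21 \
    --binning 1 --median 51 --out hm.tif
epi deproj --mask fixture/mask.tif --heightmap hm.tif \
    --dx 1 --dy 1 --dz 1 --sigma auto --out cells.csv
epi eval --proj proj.tif --truth fixture/ideal_projection.tif \
    --hm hm.tif --hm-truth fixture/hm_truth.tif --out report.json
```

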