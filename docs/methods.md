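# Methods

## Model and assumptions

The tissue layer of interest is modeled as a single-valued surface
`z = f(x, y)`: at most one surface Z per (X, Y) position. Folded
epithelia are out of scope. Stacks are calibrated grids of non-negative
intensities with pixel size `dx, dy` and slice spacing `dz` (μm); `dz`
scales every 3D measurement and is therefore never silently defaulted
when reading files (explicit argument > TIFF metadata > error, unless
the caller opts into a default).

## Height-map extraction

Per Z-plane of the designated channel: optional block **binning**
(mean aggregation over `b × b` blocks; partial edge blocks average over
the pixels they contain), optional Gaussian pre-smoothing, then a
sliding-window **mean** or **standard-deviation** response. The
standard-deviation filter responds strongly to the fine junctional
mesh of an epithelium and weakly to smooth or diffuse structures, which
is why it is the default (`filter_kind="std"`, window 21 px). Per
binned (X, Y), the height-map is the argmax over Z of the response,
ties broken toward the smallest z (closest to the objective). The map
is then **median-filtered** in binned space and bilinearly rescaled to
the full extent (binned pixel `i` is the block center `i·b + (b−1)/2`;
full-resolution coordinates sample the binned grid accordingly, clamped
at borders, so `b = 1` is the identity).

Numerical conventions, fixed for testability:

- all sliding filters (uniform, median, Gaussian) use symmetric
  reflective borders;
- the standard deviation uses population (N) normalization — the choice
  cannot move the argmax but must be pinned for oracle tests;
- Gaussian pre-smoothing applies to the *binned* plane, and the median
  runs in binned space, for cost symmetry with extraction;
- height-map values are real after rescaling; consumers must not assume
  integers.

Parameter guidance: the response window should exceed the typical cell
diameter so cell interiors (where junctional signal is absent) still
see membrane within their window; the median window must exceed the
footprint of any spurious bright structure it is meant to reject —
a bright blob of diameter `d` spreads its response over roughly
`d + filter_window` pixels, and the median removes it only if that is
a minority of the median footprint. The notum-like demonstrations in
this package use `binning=1, median_window=51` for exactly that reason
(fat-body response blobs span ≈ 35 px there).

## Local projection

Per pixel, the height-map is rounded half-up to the nearest slice `z*`,
and intensity is accumulated over `z* + offset − Δz … z* + offset + Δz`
(clipped to the stack; mean mode divides by the slices actually used).
`offset` is per-channel, so e.g. a nuclear channel can be sampled a few
slices below the junctional surface. `Δz = 0` reads exactly one slice.
Sub-slice interpolation is deliberately not performed. The MIP is
provided as the evaluation baseline only.

`project_stack` makes one pass to extract the height-map (reads each
plane of the target channel once) and one to project (each plane of
every channel once): every `(c, z)` plane is read at most twice, which
is the contract that makes streamed, larger-than-memory stacks
practical. Streaming keeps one plane in memory at a time plus the
(small) height-map; time-points are processed independently with
per-frame height-maps.

## Deprojection

The reference surface is the height-map smoothed by a Gaussian with
σ equal to the **median cell diameter** (median equivalent-area diameter
`2·sqrt(A/π)` over the mask's cells, user-overridable), scaled by `dz`,
and evaluated bilinearly. The smoothing removes the staircase pattern
of integer-slice height-maps; it also flattens any tilted surface
within ~3σ of the image border (no padding mode preserves a ramp), so
cells inside that margin carry a known bias — border-flagged cells are
excluded from summaries by default, and the validation of the planar
distortion law restricts itself to cells beyond the smoothing margin.

Cell polygons are traced along the 0.5-iso-contour of each labeled
region (pixel centers at integer 0-based indices; physical coordinates
are index × pixel size), then simplified with a 0.7 px Douglas-Peucker
tolerance: the half-pixel staircase of a digital boundary is
digitization noise, not cell shape, and simplification removes the
classical overestimation of digital perimeters. A consequence is that
tracing is not exactly equivariant under scene rotation (the traversal
start point changes), so rigid-motion checks hold to sub-pixel
digitization tolerance rather than machine precision. Boolean masks are
interpreted as junction masks (junctions True) and their complement is
labeled by 4-connected components; integer masks are label images.
Neighbors are labels whose regions come within a 2-pixel Chebyshev
reach; cells within 2 px of the image border are flagged.

Each vertex `(x, y)` lifts to `(x, y, f(x, y))`. Measurements on the
lifted contour:

- **Area.** The triangle fan about the vertex centroid is summed as a
  *vector* (half cross-products) and `a3D` is the magnitude of the sum.
  This is exact for every planar polygon, convex or not; for non-planar
  contours it measures the area of the projection along the mean
  normal. `a2D` is the z-component of the same vector sum —
  algebraically the shoelace area of the 2D polygon — which guarantees
  `a3D ≥ a2D` structurally and makes the flat-surface identity
  (`e_a = 0`) hold bitwise. (Summing triangle *magnitudes* instead
  would break exactness for non-convex planar cells, which is why the
  vector form was chosen.)
- **Perimeter.** Sum of 3D edge lengths.
- **Apical plane.** Total least squares via SVD of the centered
  vertices; the normal (smallest singular vector) is oriented with
  `n_z ≥ 0`; slope `θ = arccos|n_z| ∈ [0°, 90°]`; Euler angles in the
  Z-X'-Z'' convention for the rotation taking the XY frame onto
  (line of nodes, in-plane normal, surface normal). Flat cells are
  gimbal-locked; the third angle is set to zero.
- **Ellipse.** Vertices are projected into the fitted plane's frame and
  the unique ellipse with the polygon interior's second-order area
  moments (closed-form Green's-theorem polygon moments) is reported:
  semi-axes `a ≥ b`, eccentricity `sqrt(1 − (b/a)²)`. Orientation is
  emitted twice, deliberately: `ellipse_orientation` in the apical
  plane and `orientation_xy` from the raw 2D polygon, since either
  frame can be meant by "orientation".
- **Curvature.** Monge-patch mean and Gaussian curvature from central
  finite differences of the smoothed surface, evaluated at the cell
  centroid. Sign convention: `H > 0` for a dome (surface bulging toward
  +z); border points fall back to one-sided differences with a warning.
- **Errors.** `e_a = 1 − a2D/a3D`, `e_l = 1 − l2D/l3D`.

## Height-map sensitivity procedure

To emulate a worst-case single-cell height-map error, a uniformly
random half of each cell's contour vertices is shifted by **+1 slice**
(the direction is a fixed convention; the shift magnitude is `dz`), and
3D area and perimeter are recomputed. The report gives per-cell
relative differences and their mean ± sd. On the steep-bump fixture the
induced errors (≈ 0.8 % area, ≈ 0.7 % perimeter) are an order of
magnitude below the tilt distortion the deprojection corrects
(mean `e_a` ≈ 16 % for cells steeper than 30°).

## Synthetic fixtures

The generator emulates the three-layer structure of a fly-notum stack:
a membrane lattice (Voronoi tessellation of Poisson-disc seeds, 1-px
junction band, labels 1..n) painted 1 voxel thick at the rounded
surface slice; an auto-fluorescent cuticle sheet `cuticle_offset`
slices above the surface (toward the objective, i.e. lower z) with a
smooth random texture; fat bodies as 5–15 bright spheres of radius
2–5 px, 5–15 slices below; a separable Gaussian PSF with `σz ≥ 2·σxy`
(axial elongation); Gaussian or Poisson noise applied last. Every
fixture ships its analytic surface, sampled height-map, label mask and
ideal projection (the surface-intensity image of the membrane-only,
noise-free volume), and a seed fully determines every output.

Fixed fixture choices, made once on realism grounds:

- the notum preset uses a 2-px membrane (junctional signal is ~2 μm
  wide after staining and blur) at intensity 600; with the (1, 2) px
  PSF this peaks near 100 intensity units, and the default noise
  sd = 35 puts the membrane at SNR ≈ 3;
- notum cells average ~250 px² (≈ 18 px across), below the 21-px
  response window, so cell interiors always see junctional signal;
- the tilted-plane presets choose `dz` so the plane spans the stack's
  Z range, and the sphere-cap preset uses 0.5 μm pixels so cells stay
  ~10 px across;
- surfaces must keep `z ∈ [1, nz − 2]` slices so accumulation windows
  fit; the generator rejects specs that violate this.

What the fixtures do **not** model: realistic optics beyond a Gaussian
PSF, intensity inhomogeneity, tissue motion, segmentation errors
(masks are ground truth). Passing tests therefore demonstrate the
geometry and the projection logic, not robustness to segmentation
noise on real data.

## Validation summary (all computed by the test suite)

- Planar-cell law: `e_a = 1 − cos θ` to 1e-6 on analytic tilted planes
  (θ = 0…60°), to 0.02 through the full height-map pipeline (beyond the
  smoothing margin), monotone in θ.
- Flat surface: every 3D metric equals its 2D counterpart exactly.
- Notum-like recovery: height-map RMSE ≈ 0.4–0.6 slices at SNR ≈ 3; a
  solid bright layer on an integer staircase is recovered exactly
  (mean filter — with a textured or junction-only layer, window-majority
  effects at staircase edges make single-pixel exactness unattainable
  in principle).
- Spurious-layer rejection: noiseless local projection equals the ideal
  image exactly; with cuticle and fat bodies the local projection's
  RMSE is far below the MIP's.
- Sphere cap (R = 50 μm, h = 10 μm, ≥ 100 cells): summed interior
  3D areas within 3 % of the analytic area integral over the same
  pixels; interior cells are taken one cell diameter clear of the cap
  rim, where the fixture's piecewise surface has a kink that smoothing
  necessarily rounds.
- Curvature: `H` within 5 % of 1/R and `K` within 10 % of 1/R² at cell
  centroids on the sphere; `H ≈ 1/(2R)`, `K ≈ 0` on the cylinder.
- Streaming: every plane read at most twice during a streamed
  projection.
- Oracle battery: filters, binning, median, polygon area/perimeter,
  RMSE and neighbor counts match explicit brute-force loops on ≥ 20
  random instances each.

## Known limitations

- No sub-slice intensity interpolation in projection (rounding only).
- No mesh-based surface input; the surface is always a height-map.
- No temporal regularization across time-points.
- Reference-surface smoothing biases metrics within ~3σ of the image
  border; work at least one smoothing length inside the field of view
  or override σ.
- The moment ellipse assumes the polygon encloses its interior simply;
  self-intersecting masks produce a warning and undefined moments.
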