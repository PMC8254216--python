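"""Deprojection geometry: surface, polygons, lifting, morphometrics."""

import math

import numpy as np
import pytest

from epiproj import (CellPolygon2D, DegenerateGeometryError, ReferenceSurface,
                     build_reference_surface, deproject, fit_cell_plane,
                     fit_ellipse_3d, lift_polygon, local_curvature,
                     make_epithelium_mask, make_surface, mask_to_polygons,
                     perturb_contours, polygon_area_3d, polygon_perimeter_3d,
                     SyntheticSpec)
from epiproj.deproj import _polygon_moment_ellipse, polygon_area_2d


def square(side=1.0, z=None):
    v = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float)
    if z is None:
        return v
    return np.column_stack([v, np.asarray(z, dtype=float)])


# ---------------------------------------------------------------------------
# reference surface
# ---------------------------------------------------------------------------

def test_surface_constant_map_scaled_by_dz():
    surf = build_reference_surface(np.full((20, 20), 4.0), 5.0, 1, 1, 0.65)
    assert np.allclose(surf(np.array([3.2, 10.0]), np.array([7.7, 0.0])), 2.6)


def test_surface_smoothing_preserves_affine_ramp():
    hm = 0.1 * np.tile(np.arange(40.0), (40, 1))
    surf = ReferenceSurface(hm, 1, 1, 1, sigma_um=3.0)
    inner = surf.z_um[15:25, 15:25]
    assert np.allclose(inner, hm[15:25, 15:25], atol=1e-6)


def test_surface_smoothing_softens_staircase():
    hm = np.tile(np.repeat(np.arange(6.0), 10), (60, 1))
    surf = ReferenceSurface(hm, 1, 1, 1, sigma_um=5.0)
    row_in, row_out = hm[30], surf.z_um[30]
    assert np.all(np.diff(row_out) >= -1e-9)  # monotone
    d2_in = np.abs(np.diff(row_in, 2))
    d2_out = np.abs(np.diff(row_out, 2))
    steps = np.where(d2_in > 0.5)[0]
    assert np.all(d2_out[steps] < d2_in[steps])


def test_surface_rejects_bad_calibration():
    from epiproj import InvalidParameterError
    with pytest.raises(InvalidParameterError):
        build_reference_surface(np.zeros((5, 5)), 1.0, 1, 1, 0)
    with pytest.raises(InvalidParameterError):
        build_reference_surface(np.zeros((5, 5)), 0.0, 1, 1, 1)


# ---------------------------------------------------------------------------
# mask -> polygons
# ---------------------------------------------------------------------------

def test_square_region_area_and_border_flag():
    mask = np.zeros((20, 20), dtype=int)
    mask[5:15, 5:15] = 1
    (poly,) = mask_to_polygons(mask)
    assert abs(poly.area - 100.0) <= 10.0  # one-pixel boundary-convention slack
    assert not poly.on_border
    mask2 = np.zeros((20, 20), dtype=int)
    mask2[0:6, 0:6] = 1
    (poly2,) = mask_to_polygons(mask2)
    assert poly2.on_border


def test_adjacent_rectangles_are_neighbors():
    mask = np.zeros((12, 20), dtype=int)
    mask[3:9, 3:10] = 1
    mask[3:9, 10:17] = 2
    p1, p2 = sorted(mask_to_polygons(mask), key=lambda p: p.label)
    assert p1.neighbor_labels == {2} and p2.neighbor_labels == {1}


def test_binary_junction_mask_is_labeled():
    junctions = np.zeros((15, 15), dtype=bool)
    junctions[7, :] = True
    polys = mask_to_polygons(junctions)
    assert len(polys) == 2
    assert all(len(p.neighbor_labels) == 1 for p in polys)


def test_voronoi_neighbor_counts_match_adjacency_oracle():
    spec = SyntheticSpec(nx=80, ny=80, nz=8, z0=4, n_cells=25, seed=11)
    mask, _ = make_epithelium_mask(spec)
    polys = {p.label: p for p in mask_to_polygons(mask)}
    # brute-force region adjacency: labels within Chebyshev distance 2
    h, w = mask.shape
    oracle = {lab: set() for lab in polys}
    for y in range(h):
        for x in range(w):
            a = mask[y, x]
            if a == 0:
                continue
            for dy in (-2, -1, 0, 1, 2):
                for dx_ in (-2, -1, 0, 1, 2):
                    yy, xx = y + dy, x + dx_
                    if 0 <= yy < h and 0 <= xx < w:
                        b = mask[yy, xx]
                        if b != 0 and b != a:
                            oracle[a].add(b)
    for lab, p in polys.items():
        assert p.neighbor_labels == oracle[lab]


def test_empty_mask_warns_and_returns_nothing():
    with pytest.warns(UserWarning):
        assert mask_to_polygons(np.zeros((10, 10), dtype=int)) == []


def test_polygon_orientation_is_normalized():
    cw = np.array([[0, 0], [0, 2], [2, 2], [2, 0]], dtype=float)
    poly = CellPolygon2D(cw, label=1)
    assert poly.area > 0


# ---------------------------------------------------------------------------
# lifting
# ---------------------------------------------------------------------------

def test_lift_on_flat_surface_is_identity():
    surf = ReferenceSurface(np.zeros((30, 30)), 1, 1, 1, 0)
    poly = CellPolygon2D(5 + square(4.0), label=1)
    c3 = lift_polygon(poly, surf)
    assert np.allclose(c3[:, :2], poly.vertices) and np.allclose(c3[:, 2], 0)


def test_lift_onto_tilted_plane():
    x = np.tile(np.arange(30.0), (30, 1))
    surf = ReferenceSurface(x * math.tan(math.radians(30)), 1, 1, 1, 0)
    poly = CellPolygon2D(10 + square(1.0), label=1)
    c3 = lift_polygon(poly, surf)
    assert np.allclose(c3[:, 2], c3[:, 0] * math.tan(math.radians(30)), atol=1e-9)


def test_lift_reevaluates_surface_at_vertices(rng):
    spec = SyntheticSpec(surface_kind="gaussian_bump", nx=40, ny=40, nz=16,
                         z0=5, bump_amplitude=5, bump_width=8, seed=3)
    _, hm = make_surface(spec)
    surf = ReferenceSurface(hm, 1, 1, 1, 0)
    verts = rng.uniform(8, 30, (6, 2))
    hull_order = np.argsort(np.arctan2(*(verts - verts.mean(0)).T[::-1]))
    poly = CellPolygon2D(verts[hull_order], label=1)
    c3 = lift_polygon(poly, surf)
    assert np.allclose(c3[:, 2], surf(c3[:, 0], c3[:, 1]), atol=1e-9)


# ---------------------------------------------------------------------------
# 3D area / perimeter
# ---------------------------------------------------------------------------

def test_area_flat_square_and_tilted_rectangle():
    assert polygon_area_3d(square(1.0, [0, 0, 0, 0])) == pytest.approx(1.0)
    # unit square with one edge pair sloped at 60 deg about one side: the
    # planar cell keeps area 1 while its XY footprint shrinks to cos(60) = 0.5
    t = math.radians(60)
    tilted = np.array([[0, 0, 0], [1, 0, 0],
                       [1, math.cos(t), math.sin(t)], [0, math.cos(t), math.sin(t)]])
    assert polygon_area_3d(tilted) == pytest.approx(1.0, rel=1e-12)
    assert polygon_area_2d(tilted[:, :2]) == pytest.approx(0.5, rel=1e-12)


def test_area_matches_inplane_shoelace_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(4, 9))
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        rad = rng.uniform(1, 4, n)
        p2 = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        # embed in a random tilted plane
        theta, phi = rng.uniform(0, 1.2), rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        v = np.array([-np.sin(phi) * np.cos(theta), np.cos(phi) * np.cos(theta),
                      np.sin(theta)])
        c3 = np.outer(p2[:, 0], u) + np.outer(p2[:, 1], v) + rng.uniform(0, 5, 3)
        shoelace = abs(0.5 * np.sum(p2[:, 0] * np.roll(p2[:, 1], -1)
                                    - np.roll(p2[:, 0], -1) * p2[:, 1]))
        assert polygon_area_3d(c3) == pytest.approx(shoelace, rel=1e-9)


def test_perimeter_examples_and_oracle(rng):
    assert polygon_perimeter_3d(square(1.0, [0, 0, 0, 0])) == pytest.approx(4.0)
    lifted = square(1.0, [0, 1, 1, 0])  # two opposite edges rise by 1
    assert polygon_perimeter_3d(lifted) == pytest.approx(2 + 2 * math.sqrt(2))
    c3 = rng.uniform(0, 10, (7, 3))
    manual = sum(np.linalg.norm(c3[i] - c3[(i + 1) % 7]) for i in range(7))
    assert polygon_perimeter_3d(c3) == pytest.approx(manual, rel=1e-12)


def test_degenerate_contour_has_zero_area():
    line = np.column_stack([np.arange(4.0), np.arange(4.0), np.zeros(4)])
    with pytest.warns(UserWarning):
        assert polygon_area_3d(line) == 0.0


# ---------------------------------------------------------------------------
# plane fit
# ---------------------------------------------------------------------------

def test_plane_fit_flat_and_analytic():
    flat = fit_cell_plane(square(2.0, [0, 0, 0, 0]))
    assert flat.slope_theta == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(flat.normal, [0, 0, 1])
    t = math.radians(40)
    verts = square(2.0)
    c3 = np.column_stack([verts, verts[:, 0] * math.tan(t)])
    fit = fit_cell_plane(c3)
    assert fit.slope_theta == pytest.approx(40.0, abs=1e-6)


def test_plane_fit_euler_angles_reconstruct_rotation():
    from scipy.spatial.transform import Rotation
    t = math.radians(25)
    verts = square(2.0)
    c3 = np.column_stack([verts, verts[:, 1] * math.tan(t)])
    fit = fit_cell_plane(c3)
    R = Rotation.from_euler("ZXZ", fit.euler_angles, degrees=True).as_matrix()
    assert np.allclose(R[:, 2], fit.normal, atol=1e-9)


def test_plane_fit_recovers_jittered_plane(rng):
    t = math.radians(35)
    xy = rng.uniform(0, 10, (40, 2))
    z = xy[:, 0] * math.tan(t) + rng.normal(0, 0.05, 40)
    fit = fit_cell_plane(np.column_stack([xy, z]))
    assert fit.slope_theta == pytest.approx(35.0, abs=1.0)


def test_plane_fit_rejects_collinear_points():
    line = np.column_stack([np.arange(5.0), 2 * np.arange(5.0), np.zeros(5)])
    with pytest.raises(DegenerateGeometryError):
        fit_cell_plane(line)


# ---------------------------------------------------------------------------
# ellipse fit
# ---------------------------------------------------------------------------

def regular_ngon(n, r):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def test_ellipse_of_circle_and_rectangle():
    circle = _polygon_moment_ellipse(regular_ngon(64, 3.0))
    assert circle.a == pytest.approx(3.0, rel=2e-3)
    assert circle.b == pytest.approx(3.0, rel=2e-3)
    assert circle.eccentricity < 0.02
    rect = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], dtype=float)
    fit = _polygon_moment_ellipse(rect)
    assert fit.eccentricity == pytest.approx(math.sqrt(1 - 0.25), rel=1e-9)
    assert abs(fit.orientation) < 1e-6  # long axis along x


def test_inplane_ellipse_removes_tilt_foreshortening():
    t = math.radians(60)
    p2 = regular_ngon(64, 2.0)
    c3 = np.column_stack([p2[:, 0], p2[:, 1] * math.cos(t), p2[:, 1] * math.sin(t)])
    plane = fit_cell_plane(c3)
    inplane = fit_ellipse_3d(c3, plane)
    assert inplane.eccentricity < 0.02
    projected = _polygon_moment_ellipse(c3[:, :2])
    assert projected.eccentricity == pytest.approx(math.sqrt(1 - 0.25), abs=5e-3)


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def test_flat_surface_has_zero_curvature():
    surf = ReferenceSurface(np.full((30, 30), 3.0), 1, 1, 1, 0)
    H, K = local_curvature(surf, (15.0, 15.0))
    assert H == pytest.approx(0.0, abs=1e-12)
    assert K == pytest.approx(0.0, abs=1e-12)


def test_sphere_curvature_analytic():
    R, h = 50.0, 10.0
    spec = SyntheticSpec(surface_kind="sphere_cap", cap_R=R, cap_h=h,
                         nx=120, ny=120, dx=0.5, dy=0.5, nz=16, z0=2, seed=0)
    _, hm = make_surface(spec)
    surf = ReferenceSurface(hm, 0.5, 0.5, 1.0, sigma_um=0)
    cx = (120 - 1) * 0.5 / 2
    H, K = surf.curvature(cx, cx)
    assert abs(H - 1 / R) / (1 / R) < 0.05
    assert abs(K - 1 / R ** 2) / (1 / R ** 2) < 0.10
    assert H > 0  # dome-positive sign convention


def test_cylinder_curvature_analytic():
    R = 50.0
    spec = SyntheticSpec(surface_kind="cylinder", cap_R=R, cap_h=10.0,
                         nx=120, ny=120, dx=0.5, dy=0.5, nz=16, z0=2, seed=0)
    _, hm = make_surface(spec)
    surf = ReferenceSurface(hm, 0.5, 0.5, 1.0, sigma_um=0)
    cx = (120 - 1) * 0.5 / 2
    H, K = surf.curvature(cx, cx)
    assert abs(H - 1 / (2 * R)) / (1 / (2 * R)) < 0.05
    assert abs(K) < 0.1 / R ** 2


# ---------------------------------------------------------------------------
# deproject end-to-end
# ---------------------------------------------------------------------------

def voronoi_fixture(surface_kind="flat", **kw):
    spec = SyntheticSpec(surface_kind=surface_kind, nx=64, ny=64, nz=8, z0=4,
                         n_cells=16, seed=21, **kw)
    _, hm = make_surface(spec)
    mask, _ = make_epithelium_mask(spec)
    return spec, mask, hm


def test_flat_surface_identity():
    """On a flat surface every 3D metric equals its 2D counterpart."""
    _, mask, hm = voronoi_fixture()
    cells = deproject(mask, hm, 1, 1, 0.65)
    assert cells
    for c in cells:
        assert c.err_area == pytest.approx(0.0, abs=1e-12)
        assert c.err_perim == pytest.approx(0.0, abs=1e-12)
        assert c.slope_theta == pytest.approx(0.0, abs=1e-9)
        assert c.area_3d == pytest.approx(c.area_2d, rel=1e-12)
        assert c.perim_3d == pytest.approx(c.perim_2d, rel=1e-12)


def test_planar_cells_follow_the_cosine_law():
    """e_a = 1 - cos(theta) for cells on an exactly planar tilted surface."""
    theta = 60.0
    x = np.tile(np.arange(64.0), (64, 1)) * math.tan(math.radians(theta))
    spec, mask, _ = voronoi_fixture()
    surf = ReferenceSurface(x, 1, 1, 1, sigma_um=0)
    cells = deproject(mask, x, 1, 1, 1, surface=surf)
    for c in cells:
        if not c.on_border:
            assert c.err_area == pytest.approx(0.5, abs=1e-9)
            assert c.slope_theta == pytest.approx(theta, abs=1e-6)


def test_bump_fixture_area_consistency():
    spec, mask, hm = voronoi_fixture("gaussian_bump", bump_amplitude=2.0,
                                     bump_width=20.0)
    cells = deproject(mask, hm, 1, 1, 1)
    for c in cells:
        pix = int(np.sum(mask == c.label))
        # polygon area and pixel count agree within the boundary convention
        assert abs(c.area_2d - pix) <= 0.25 * c.perim_2d + 2
        assert c.area_3d >= c.area_2d - 1e-12


def test_error_monotone_in_slope():
    spec, mask, _ = voronoi_fixture()
    means = []
    for theta in (0, 15, 30, 45, 60):
        z = np.tile(np.arange(64.0), (64, 1)) * math.tan(math.radians(theta))
        surf = ReferenceSurface(z, 1, 1, 1, sigma_um=0)
        cells = deproject(mask, z, 1, 1, 1, surface=surf)
        means.append(np.mean([c.err_area for c in cells if not c.on_border]))
    assert np.all(np.diff(means) > 0)


def test_rotation_about_z_preserves_metrics():
    spec, mask, hm = voronoi_fixture("gaussian_bump", bump_amplitude=2.0,
                                     bump_width=20.0)
    cells = deproject(mask, hm, 1, 1, 1)
    cells_rot = deproject(np.rot90(mask).copy(), np.rot90(hm).copy(), 1, 1, 1)
    a = {c.label: c for c in cells}
    b = {c.label: c for c in cells_rot}
    assert set(a) == set(b)
    for lab in a:
        if a[lab].on_border:
            continue
        # boundary tracing/simplification is start-point dependent, so the
        # polygons agree only to sub-pixel digitization tolerance
        assert a[lab].area_3d == pytest.approx(b[lab].area_3d, rel=0.03)
        assert a[lab].perim_3d == pytest.approx(b[lab].perim_3d, rel=0.03)
        assert a[lab].eccentricity == pytest.approx(b[lab].eccentricity, abs=0.05)
        assert a[lab].mean_curvature == pytest.approx(b[lab].mean_curvature, abs=1e-3)


def test_shape_mismatch_raises():
    from epiproj import InvalidInputError
    with pytest.raises(InvalidInputError):
        deproject(np.ones((10, 10), dtype=int), np.zeros((8, 8)), 1, 1, 1)


# ---------------------------------------------------------------------------
# perturbation sensitivity
# ---------------------------------------------------------------------------

def test_perturbation_zero_shift_is_exact():
    _, mask, hm = voronoi_fixture()
    cells = deproject(mask, hm, 1, 1, 1)
    rep = perturb_contours(cells, dz_slice=0.0, seed=5)
    assert np.all(rep.area_rel_diff == 0.0)
    assert np.all(rep.perim_rel_diff == 0.0)


def test_perturbed_square_matches_hand_geometry():
    """10 μm flat square, 2 of 4 vertices raised by 0.65 μm."""
    from epiproj import DeprojectedCell
    c3 = square(10.0, [0, 0, 0, 0])
    cell_kwargs = dict(
        label=1, contour2d=c3[:, :2], contour3d=c3, area_2d=100.0,
        area_3d=polygon_area_3d(c3), perim_2d=40.0,
        perim_3d=polygon_perimeter_3d(c3), centroid3d=c3.mean(0),
        normal=np.array([0, 0, 1.0]), slope_theta=0.0,
        euler_angles=(0, 0, 0), ellipse_semi_axes=(1, 1),
        ellipse_orientation=0.0, orientation_xy=0.0, eccentricity=0.0,
        n_neighbors=0, mean_curvature=0.0, gaussian_curvature=0.0,
        err_area=0.0, err_perim=0.0, on_border=False)
    cell = DeprojectedCell(**cell_kwargs)
    rep = perturb_contours([cell], dz_slice=0.65, seed=3)
    # recompute with the same rng to know which two vertices moved
    idx = np.random.default_rng(3).choice(4, size=2, replace=False)
    pert = c3.copy()
    pert[idx, 2] += 0.65
    assert rep.area_rel_diff[0] == pytest.approx(
        abs(polygon_area_3d(pert) - 100.0) / 100.0, rel=1e-12)
    assert rep.perim_rel_diff[0] == pytest.approx(
        abs(polygon_perimeter_3d(pert) - 40.0) / 40.0, rel=1e-12)


def test_perturbation_is_seed_reproducible():
    _, mask, hm = voronoi_fixture("gaussian_bump", bump_amplitude=2.0,
                                  bump_width=15.0)
    cells = deproject(mask, hm, 1, 1, 1)
    r1 = perturb_contours(cells, 1.0, seed=9)
    r2 = perturb_contours(cells, 1.0, seed=9)
    r3 = perturb_contours(cells, 1.0, seed=10)
    assert np.array_equal(r1.area_rel_diff, r2.area_rel_diff)
    assert not np.array_equal(r1.area_rel_diff, r3.area_rel_diff)
    assert r1.mean_area_err > 0 and r1.mean_perim_err > 0
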