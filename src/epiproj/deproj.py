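"""Deprojection: distortion-corrected 3D morphometrics of epithelial cells.

A 2D segmentation measured on a projection underestimates cell area and
perimeter wherever the tissue is tilted with respect to the imaging
plane: a planar cell whose apical plane makes an angle θ with XY has its
projected area scaled by cos θ, so the relative area error is
``e_a = 1 - a2D/a3D = 1 - cos θ``.  This module undoes that distortion
by lifting each 2D cell polygon onto the reference surface
``z = f(x, y)`` and measuring on the lifted 3D contour.

Workflow (:func:`deproject`): label mask → cell polygons (μm) →
reference surface from the height-map (Gaussian-smoothed with σ equal
to the median cell diameter, to remove the staircase left by integer
Z-slice positions) → lifted 3D contours → per-cell metrics: 2D/3D area
and perimeter, fitted apical plane (normal, slope, Euler angles),
moment-equivalent ellipse in the apical plane, neighbor count, local
mean and Gaussian surface curvature, and the error metrics
``e_a = 1 - a2D/a3D`` and ``e_l = 1 - l2D/l3D``.

Conventions: pixel centers at integer indices (0-based); physical
coordinates are index × pixel size; all lengths in μm.  Mean curvature
is positive for a dome (surface bulging toward +z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.measure import approximate_polygon, find_contours, regionprops

from .errors import DegenerateGeometryError, InvalidInputError, InvalidParameterError

__all__ = [
    "ReferenceSurface",
    "CellPolygon2D",
    "DeprojectedCell",
    "PerturbationReport",
    "build_reference_surface",
    "mask_to_polygons",
    "lift_polygon",
    "polygon_area_2d",
    "polygon_perimeter_2d",
    "polygon_area_3d",
    "polygon_perimeter_3d",
    "fit_cell_plane",
    "fit_ellipse_3d",
    "local_curvature",
    "deproject",
    "perturb_contours",
]


# ---------------------------------------------------------------------------
# Reference surface
# ---------------------------------------------------------------------------

class ReferenceSurface:
    """Continuous single-valued surface ``z = f(x, y)`` in μm.

    Built from a discrete height-map (slice units) by Gaussian smoothing
    followed by bilinear interpolation, with voxel calibration applied.
    Queries outside the grid are clamped to the domain boundary.
    """

    def __init__(self, hm: np.ndarray, dx: float, dy: float, dz: float,
                 sigma_um: float = 0.0):
        for v, name in ((dx, "dx"), (dy, "dy"), (dz, "dz")):
            if not v > 0:
                raise InvalidParameterError(f"calibration {name} must be positive, got {v}")
        hm = np.asarray(hm, dtype=np.float64)
        if sigma_um > 0:
            smoothed = ndimage.gaussian_filter(
                hm, sigma=(sigma_um / dy, sigma_um / dx), mode="reflect")
        else:
            smoothed = hm.copy()
        self.dx, self.dy, self.dz = float(dx), float(dy), float(dz)
        self.sigma_um = float(sigma_um)
        self.z_um = smoothed * dz  # (y, x) grid of z in μm
        ny, nx = self.z_um.shape
        self._ys = np.arange(ny) * self.dy
        self._xs = np.arange(nx) * self.dx
        self._interp = RegularGridInterpolator(
            (self._ys, self._xs), self.z_um, method="linear")
        self._curv = None

    @property
    def x_max(self) -> float:
        return self._xs[-1]

    @property
    def y_max(self) -> float:
        return self._ys[-1]

    def __call__(self, x, y):
        """Bilinear z (μm) at physical coordinates (x, y) μm, clamped to the domain."""
        x = np.clip(np.asarray(x, dtype=np.float64), 0.0, self.x_max)
        y = np.clip(np.asarray(y, dtype=np.float64), 0.0, self.y_max)
        return self._interp(np.stack([y, x], axis=-1))

    def _curvature_grids(self):
        if self._curv is None:
            z = self.z_um
            fy, fx = np.gradient(z, self.dy, self.dx)
            fyy, fyx = np.gradient(fy, self.dy, self.dx)
            fxy, fxx = np.gradient(fx, self.dy, self.dx)
            fxy = 0.5 * (fxy + fyx)
            g = 1.0 + fx * fx + fy * fy
            # sign flipped so that a dome (local z maximum) has H > 0
            H = -(((1 + fy * fy) * fxx - 2 * fx * fy * fxy + (1 + fx * fx) * fyy)
                  / (2.0 * g ** 1.5))
            K = (fxx * fyy - fxy * fxy) / (g * g)
            self._curv = (
                RegularGridInterpolator((self._ys, self._xs), H, method="linear"),
                RegularGridInterpolator((self._ys, self._xs), K, method="linear"),
            )
        return self._curv

    def curvature(self, x: float, y: float) -> tuple[float, float]:
        """Mean and Gaussian curvature (μm⁻¹, μm⁻²) at (x, y) μm.

        Central finite differences on the smoothed grid; points on the
        border fall back to the one-sided differences of the edge rows.
        """
        if not (0 <= x <= self.x_max and 0 <= y <= self.y_max):
            warnings.warn("curvature query outside surface domain; clamped to border")
        xq = float(np.clip(x, 0.0, self.x_max))
        yq = float(np.clip(y, 0.0, self.y_max))
        if (xq < self.dx or xq > self.x_max - self.dx
                or yq < self.dy or yq > self.y_max - self.dy):
            warnings.warn("curvature at grid border uses one-sided differences")
        Hi, Ki = self._curvature_grids()
        pt = np.array([[yq, xq]])
        return float(Hi(pt)[0]), float(Ki(pt)[0])


def build_reference_surface(hm: np.ndarray, median_cell_diameter: float,
                            dx: float, dy: float, dz: float) -> ReferenceSurface:
    """Smooth a height-map into a continuous surface.

    ``median_cell_diameter`` (μm) sets the Gaussian σ, which removes the
    step-wise pattern of integer Z-slice height-maps without eroding
    structure at scales above one cell.
    """
    if not median_cell_diameter > 0:
        raise InvalidParameterError(
            f"median_cell_diameter must be > 0, got {median_cell_diameter}")
    return ReferenceSurface(hm, dx, dy, dz, sigma_um=median_cell_diameter)


def local_curvature(surface: ReferenceSurface, point) -> tuple[float, float]:
    """Mean and Gaussian curvature of the surface at ``point = (x, y)`` μm."""
    return surface.curvature(point[0], point[1])


# ---------------------------------------------------------------------------
# Polygons from segmentation masks
# ---------------------------------------------------------------------------

@dataclass
class CellPolygon2D:
    """One cell's 2D outline in μm: closed, counter-clockwise, signed area > 0."""

    vertices: np.ndarray  # (N, 2) of (x, y), not repeating the first vertex
    label: int
    neighbor_labels: set = field(default_factory=set)
    on_border: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidInputError("polygon needs at least 3 (x, y) vertices")
        if _shoelace(v) < 0:
            v = v[::-1].copy()
        if _shoelace(v) <= 0:
            raise InvalidInputError(f"polygon for label {self.label} has zero area")
        self.vertices = v
        if not _ShapelyPolygon(v).is_valid:
            warnings.warn(f"polygon for label {self.label} is self-intersecting")

    @property
    def area(self) -> float:
        return _shoelace(self.vertices)

    @property
    def perimeter(self) -> float:
        return polygon_perimeter_2d(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return _polygon_centroid(self.vertices)


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(v: np.ndarray) -> np.ndarray:
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_area_2d(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a closed 2D polygon (μm²)."""
    return abs(_shoelace(np.asarray(vertices, dtype=np.float64)))


def polygon_perimeter_2d(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=np.float64)
    return float(np.sum(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)))


def _region_adjacency(labels: np.ndarray, reach: int = 2) -> dict[int, set]:
    """Labels whose regions come within `reach` pixels (Chebyshev) of each other."""
    labels = np.asarray(labels)
    h, w = labels.shape
    adj: dict[int, set] = {}
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            if di == 0 and dj == 0:
                continue
            a = labels[max(di, 0):h + min(di, 0), max(dj, 0):w + min(dj, 0)]
            b = labels[max(-di, 0):h + min(-di, 0), max(-dj, 0):w + min(-dj, 0)]
            sel = (a > 0) & (b > 0) & (a != b)
            if not sel.any():
                continue
            pairs = np.unique(a[sel].astype(np.int64) * (labels.max() + 1) + b[sel])
            for p in pairs:
                la, lb = int(p // (labels.max() + 1)), int(p % (labels.max() + 1))
                adj.setdefault(la, set()).add(lb)
                adj.setdefault(lb, set()).add(la)
    return adj


def mask_to_polygons(mask: np.ndarray, dx: float = 1.0, dy: float = 1.0,
                     border_margin: int = 2,
                     simplify_tol_px: float = 0.7) -> list[CellPolygon2D]:
    """Trace one polygon per labeled region of a segmentation mask.

    ``mask`` is either an integer label image (0 = background/junctions)
    or a boolean junction mask (junctions True), in which case the
    non-junction regions are labeled by connected components first.  Vertices are in μm, traced
    along the 0.5-iso-contour of each region (sub-pixel, half a pixel
    outside the extreme pixel centers) and simplified with a sub-pixel
    Douglas-Peucker tolerance: the half-pixel staircase of a digital
    boundary is digitization noise, not cell shape, and straightening
    it removes the classical overestimation of digital perimeters.
    ``neighbor_labels`` holds the labels whose regions touch within a
    2-pixel reach; cells coming within ``border_margin`` pixels of the
    image border are flagged.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        # binary junction mask: junctions are foreground, cells are the gaps
        mask, _ = ndimage.label(~mask,
                                structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    labels = mask.astype(np.int64)
    if labels.max() == 0:
        warnings.warn("mask contains no labeled regions")
        return []
    adj = _region_adjacency(labels)
    h, w = labels.shape
    polys: list[CellPolygon2D] = []
    for rp in regionprops(labels):
        lab = rp.label
        sl = rp.slice
        crop = np.pad((labels[sl] == lab).astype(np.float64), 1)
        contours = find_contours(crop, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        if simplify_tol_px > 0:
            contour = approximate_polygon(contour, simplify_tol_px)
        if np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        if len(contour) < 3:
            warnings.warn(f"region {lab} too small to trace; skipped")
            continue
        rows = contour[:, 0] - 1 + sl[0].start
        cols = contour[:, 1] - 1 + sl[1].start
        verts = np.column_stack([cols * dx, rows * dy])
        on_border = (rp.bbox[0] < border_margin or rp.bbox[1] < border_margin
                     or rp.bbox[2] > h - border_margin or rp.bbox[3] > w - border_margin)
        try:
            polys.append(CellPolygon2D(verts, lab, adj.get(lab, set()), on_border))
        except InvalidInputError:
            warnings.warn(f"region {lab} has a degenerate outline; skipped")
    return polys


# ---------------------------------------------------------------------------
# Lifting and 3D measurements
# ---------------------------------------------------------------------------

def lift_polygon(poly: CellPolygon2D, surface: ReferenceSurface) -> np.ndarray:
    """Lift a 2D polygon onto the surface: (x, y) → (x, y, f(x, y)), order kept."""
    v = poly.vertices
    out = (v[:, 0] < 0) | (v[:, 0] > surface.x_max) | \
          (v[:, 1] < 0) | (v[:, 1] > surface.y_max)
    if out.any():
        warnings.warn(
            f"{int(out.sum())} vertices of cell {poly.label} fall outside the "
            "surface domain and were clamped")
    z = surface(v[:, 0], v[:, 1])
    return np.column_stack([v[:, 0], v[:, 1], z])


def _area_vector(contour3d: np.ndarray) -> np.ndarray:
    v = np.asarray(contour3d, dtype=np.float64)
    c = v.mean(axis=0)
    d = v - c
    return 0.5 * np.cross(d, np.roll(d, -1, axis=0)).sum(axis=0)


def polygon_area_3d(contour3d: np.ndarray) -> float:
    """Area (μm²) of a closed 3D contour via the vector area of its centroid fan.

    The triangle fan about the vertex centroid is summed as vectors
    (half cross-products) and the magnitude of the sum is returned.
    This is exact for every planar polygon, convex or not, and for
    non-planar contours measures the area of the projection along the
    mean normal — which guarantees ``a3D >= a2D`` (the XY-projected
    area is the z-component of the same vector sum).
    """
    v = np.asarray(contour3d, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
        raise InvalidInputError("3D contour needs at least 3 (x, y, z) vertices")
    area = float(np.linalg.norm(_area_vector(v)))
    if area == 0.0:
        warnings.warn("degenerate (collinear) 3D contour; area 0")
    return area


def polygon_perimeter_3d(contour3d: np.ndarray) -> float:
    """Perimeter (μm): sum of Euclidean edge lengths of the closed 3D contour."""
    v = np.asarray(contour3d, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
        raise InvalidInputError("3D contour needs at least 3 (x, y, z) vertices")
    return float(np.sum(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)))


@dataclass
class PlaneFit:
    """Total-least-squares plane through a 3D contour's vertices."""

    normal: np.ndarray          # unit, n_z >= 0
    slope_theta: float          # degrees, angle between plane and XY, in [0, 90]
    euler_angles: tuple[float, float, float]  # Z-X'-Z'' degrees
    centroid: np.ndarray
    u: np.ndarray               # in-plane axis (line of nodes)
    v: np.ndarray               # in-plane axis completing the right-handed frame


def fit_cell_plane(contour3d: np.ndarray) -> PlaneFit:
    """Fit the apical plane of a cell: TLS via the vertex covariance.

    The normal is the eigenvector of the smallest covariance eigenvalue,
    oriented with a non-negative z-component; the slope is
    ``arccos(|n_z|)``; Euler angles use the Z-X'-Z'' convention for the
    rotation taking the XY-plane frame onto the fitted-plane frame.
    """
    pts = np.asarray(contour3d, dtype=np.float64)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 vertices")
    c = pts.mean(axis=0)
    _, s, wt = np.linalg.svd(pts - c, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError("vertices are collinear; no unique plane")
    n = wt[2]
    if n[2] < 0:
        n = -n
    slope = float(np.degrees(np.arccos(np.clip(abs(n[2]), 0.0, 1.0))))
    zaxis = np.array([0.0, 0.0, 1.0])
    line = np.cross(zaxis, n)
    if np.linalg.norm(line) < 1e-12:
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = line / np.linalg.norm(line)
    vv = np.cross(n, u)
    R = np.column_stack([u, vv, n])
    with warnings.catch_warnings():
        # flat cells are gimbal-locked in Z-X'-Z''; scipy's fallback (third
        # angle zero) is the convention we want
        warnings.simplefilter("ignore", UserWarning)
        euler = tuple(Rotation.from_matrix(R).as_euler("ZXZ", degrees=True))
    return PlaneFit(normal=n, slope_theta=slope, euler_angles=euler,
                    centroid=c, u=u, v=vv)


@dataclass
class EllipseFit:
    """Moment-equivalent ellipse of a polygon interior."""

    a: float                # semi-major axis, a >= b
    b: float
    orientation: float      # degrees of the major axis in the measurement frame, (-90, 90]
    eccentricity: float     # sqrt(1 - (b/a)^2)


def _polygon_moment_ellipse(v2: np.ndarray) -> EllipseFit:
    """Ellipse with the same area second moments as the 2D polygon interior."""
    x, y = v2[:, 0], v2[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    if a < 0:
        return _polygon_moment_ellipse(v2[::-1])
    if abs(a) < 1e-12:
        raise DegenerateGeometryError("polygon has zero area; no ellipse fit")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    ixx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    iyy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    cov = np.array([[ixx - a * cx * cx, ixy - a * cx * cy],
                    [ixy - a * cx * cy, iyy - a * cy * cy]]) / a
    evals, evecs = np.linalg.eigh(cov)
    lo, hi = max(evals[0], 0.0), max(evals[1], 0.0)
    semi_a, semi_b = 2.0 * np.sqrt(hi), 2.0 * np.sqrt(lo)
    major = evecs[:, 1]
    ang = np.degrees(np.arctan2(major[1], major[0]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    ecc = float(np.sqrt(max(0.0, 1.0 - (semi_b / semi_a) ** 2))) if semi_a > 0 else 0.0
    return EllipseFit(a=float(semi_a), b=float(semi_b), orientation=float(ang),
                      eccentricity=ecc)


def fit_ellipse_3d(contour3d: np.ndarray, plane: PlaneFit) -> EllipseFit:
    """Moment-equivalent ellipse of the cell measured in its apical plane.

    Vertices are projected into the fitted plane's (u, v) frame, where
    the tilt foreshortening is absent, and the unique ellipse with the
    same second-order area moments as the polygon interior is returned.
    """
    pts = np.asarray(contour3d, dtype=np.float64) - plane.centroid
    v2 = np.column_stack([pts @ plane.u, pts @ plane.v])
    return _polygon_moment_ellipse(v2)


# ---------------------------------------------------------------------------
# Full deprojection
# ---------------------------------------------------------------------------

@dataclass
class DeprojectedCell:
    """One cell with its lifted contour and every corrected metric."""

    label: int
    contour2d: np.ndarray
    contour3d: np.ndarray
    area_2d: float
    area_3d: float
    perim_2d: float
    perim_3d: float
    centroid3d: np.ndarray
    normal: np.ndarray
    slope_theta: float
    euler_angles: tuple[float, float, float]
    ellipse_semi_axes: tuple[float, float]
    ellipse_orientation: float      # major-axis angle in the fitted apical plane
    orientation_xy: float           # major-axis angle of the 2D polygon, XY frame
    eccentricity: float
    n_neighbors: int
    mean_curvature: float
    gaussian_curvature: float
    err_area: float                 # e_a = 1 - a2D/a3D
    err_perim: float                # e_l = 1 - l2D/l3D
    on_border: bool

    def to_row(self) -> dict:
        """Flat dict of scalar metrics, one CSV row."""
        return {
            "label": self.label,
            "area_2d": self.area_2d,
            "area_3d": self.area_3d,
            "perim_2d": self.perim_2d,
            "perim_3d": self.perim_3d,
            "centroid_x": self.centroid3d[0],
            "centroid_y": self.centroid3d[1],
            "centroid_z": self.centroid3d[2],
            "normal_x": self.normal[0],
            "normal_y": self.normal[1],
            "normal_z": self.normal[2],
            "slope_theta": self.slope_theta,
            "euler_alpha": self.euler_angles[0],
            "euler_beta": self.euler_angles[1],
            "euler_gamma": self.euler_angles[2],
            "ellipse_a": self.ellipse_semi_axes[0],
            "ellipse_b": self.ellipse_semi_axes[1],
            "ellipse_orientation": self.ellipse_orientation,
            "orientation_xy": self.orientation_xy,
            "eccentricity": self.eccentricity,
            "n_neighbors": self.n_neighbors,
            "mean_curvature": self.mean_curvature,
            "gaussian_curvature": self.gaussian_curvature,
            "err_area": self.err_area,
            "err_perim": self.err_perim,
            "on_border": self.on_border,
        }


def estimate_median_cell_diameter(polys: list[CellPolygon2D]) -> float:
    """Median equivalent-area diameter 2·sqrt(A/π) over all cells (μm)."""
    if not polys:
        raise InvalidInputError("no cells to estimate a diameter from")
    return float(np.median([2.0 * np.sqrt(p.area / np.pi) for p in polys]))


def deproject(mask: np.ndarray, hm: np.ndarray, dx: float, dy: float, dz: float,
              median_cell_diameter: float | None = None,
              surface: ReferenceSurface | None = None) -> list[DeprojectedCell]:
    """Deproject a 2D segmentation onto the reference surface.

    ``median_cell_diameter`` (μm) sets the surface smoothing σ; when
    None it is estimated from the mask as the median equivalent-area
    diameter.  A prebuilt ``surface`` (e.g. an analytic one) overrides
    the height-map smoothing entirely.  Cells touching the image border
    are still measured but flagged ``on_border`` so summary statistics
    can exclude them.
    """
    mask = np.asarray(mask)
    hm = np.asarray(hm, dtype=np.float64)
    if surface is None and mask.shape != hm.shape:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match height-map shape {hm.shape}")
    polys = mask_to_polygons(mask, dx=dx, dy=dy)
    if not polys:
        return []
    if surface is None:
        if median_cell_diameter is None:
            median_cell_diameter = estimate_median_cell_diameter(polys)
        surface = build_reference_surface(hm, median_cell_diameter, dx, dy, dz)
    cells: list[DeprojectedCell] = []
    for poly in polys:
        c3 = lift_polygon(poly, surface)
        # a2D is the XY projection of the same vector-area accumulation as
        # a3D (algebraically the shoelace area), so a flat surface gives
        # bitwise-identical 2D and 3D areas
        vec = _area_vector(c3)
        a2 = abs(float(vec[2]))
        l2 = poly.perimeter
        a3 = float(np.linalg.norm(vec))
        l3 = polygon_perimeter_3d(c3)
        try:
            plane = fit_cell_plane(c3)
            ellipse = fit_ellipse_3d(c3, plane)
        except DegenerateGeometryError:
            warnings.warn(f"cell {poly.label} has degenerate geometry; skipped")
            continue
        flat = _polygon_moment_ellipse(poly.vertices)
        cen2 = poly.centroid
        H, K = surface.curvature(cen2[0], cen2[1])
        cells.append(DeprojectedCell(
            label=poly.label,
            contour2d=poly.vertices,
            contour3d=c3,
            area_2d=a2,
            area_3d=a3,
            perim_2d=l2,
            perim_3d=l3,
            centroid3d=c3.mean(axis=0),
            normal=plane.normal,
            slope_theta=plane.slope_theta,
            euler_angles=plane.euler_angles,
            ellipse_semi_axes=(ellipse.a, ellipse.b),
            ellipse_orientation=ellipse.orientation,
            orientation_xy=flat.orientation,
            eccentricity=ellipse.eccentricity,
            n_neighbors=len(poly.neighbor_labels),
            mean_curvature=H,
            gaussian_curvature=K,
            err_area=1.0 - a2 / a3 if a3 > 0 else 0.0,
            err_perim=1.0 - l2 / l3 if l3 > 0 else 0.0,
            on_border=poly.on_border,
        ))
    return cells


# ---------------------------------------------------------------------------
# Height-map perturbation sensitivity
# ---------------------------------------------------------------------------

@dataclass
class PerturbationReport:
    """Sensitivity of 3D metrics to a one-slice error on half of each contour."""

    labels: list[int]
    area_rel_diff: np.ndarray       # per-cell |Δa3D| / a3D
    perim_rel_diff: np.ndarray      # per-cell |Δl3D| / l3D
    mean_area_err: float
    sd_area_err: float
    mean_perim_err: float
    sd_perim_err: float


def perturb_contours(cells: list[DeprojectedCell], dz_slice: float,
                     seed: int = 0) -> PerturbationReport:
    """Shift a random half of each cell's contour vertices by +``dz_slice`` μm in z.

    Emulates a worst-case height-map error at the single-cell scale:
    half the boundary points move one Z-slice, the other half stay.
    3D area and perimeter are recomputed on the perturbed contour and
    per-cell relative differences are reported with their mean ± sd.
    """
    if dz_slice < 0:
        raise InvalidParameterError(f"dz_slice must be >= 0, got {dz_slice}")
    rng = np.random.default_rng(seed)
    labels, da, dl = [], [], []
    for cell in cells:
        n = cell.contour3d.shape[0]
        if n < 4:
            warnings.warn(f"cell {cell.label} has fewer than 4 vertices; skipped")
            continue
        idx = rng.choice(n, size=n // 2, replace=False)
        pert = cell.contour3d.copy()
        pert[idx, 2] += dz_slice
        a3 = polygon_area_3d(pert)
        l3 = polygon_perimeter_3d(pert)
        labels.append(cell.label)
        da.append(abs(a3 - cell.area_3d) / cell.area_3d if cell.area_3d > 0 else 0.0)
        dl.append(abs(l3 - cell.perim_3d) / cell.perim_3d if cell.perim_3d > 0 else 0.0)
    da = np.asarray(da)
    dl = np.asarray(dl)
    return PerturbationReport(
        labels=labels,
        area_rel_diff=da,
        perim_rel_diff=dl,
        mean_area_err=float(da.mean()) if da.size else 0.0,
        sd_area_err=float(da.std()) if da.size else 0.0,
        mean_perim_err=float(dl.mean()) if dl.size else 0.0,
        sd_perim_err=float(dl.std()) if dl.size else 0.0,
    )
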