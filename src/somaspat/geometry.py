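"""Bounded 3D regions, point patterns, and uniform sampling under exclusions.

All coordinates and lengths are in micrometers (µm); volumes are reported in
cubic millimeters (mm³).  The coordinate frame follows the convention
X = 0 at the most lateral point of the right side, Y = 0 most anterior,
Z = 0 most dorsal.

A :class:`Region3D` is a bounded domain with a deterministic membership test,
a volume, and an optional set of exclusion zones (sub-volumes that points may
not occupy, e.g. axonal fiber bundles).  Concrete regions are analytic shapes
(box, ball, ellipsoid), tetrahedral complexes built from point clouds
(convex hull or alpha complex), or voxel masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay

UM3_PER_MM3 = 1e9


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


# ---------------------------------------------------------------------------
# Point patterns
# ---------------------------------------------------------------------------

@dataclass
class PointPattern3D:
    """Soma centroids in µm with optional region/hemisphere/diameter labels.

    ``coords`` is an (n, 3) float array.  Labels, when present, are length-n
    object/float arrays aligned with the rows of ``coords``.
    """

    coords: np.ndarray
    region: Optional[np.ndarray] = None
    hemisphere: Optional[np.ndarray] = None
    diameter_um: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("point pattern contains non-finite coordinates")
        for name in ("region", "hemisphere", "diameter_um"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape[0] != self.n:
                    raise GeometryError(f"label array {name!r} length mismatch")
                setattr(self, name, val)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def subset(self, mask: np.ndarray) -> "PointPattern3D":
        """Row-subset the pattern (boolean mask or index array)."""
        return PointPattern3D(
            self.coords[mask],
            None if self.region is None else self.region[mask],
            None if self.hemisphere is None else self.hemisphere[mask],
            None if self.diameter_um is None else self.diameter_um[mask],
        )

    def validate_in(self, region: "Region3D", honor_exclusions: bool = True) -> None:
        """Raise unless every point passes the region's membership test."""
        ok = region.contains(self.coords, honor_exclusions=honor_exclusions)
        if not np.all(ok):
            bad = int(np.flatnonzero(~ok)[0])
            raise GeometryError(
                f"{int((~ok).sum())} points outside region {region.name!r} "
                f"(first offending row {bad})"
            )


def concatenate_patterns(patterns: Sequence[PointPattern3D]) -> PointPattern3D:
    """Stack patterns; label arrays are kept only if present on all parts."""
    coords = np.vstack([p.coords for p in patterns]) if patterns else np.empty((0, 3))

    def _cat(attr):
        vals = [getattr(p, attr) for p in patterns]
        if any(v is None for v in vals) or not vals:
            return None
        return np.concatenate(vals)

    return PointPattern3D(coords, _cat("region"), _cat("hemisphere"), _cat("diameter_um"))


# ---------------------------------------------------------------------------
# Exclusion zones
# ---------------------------------------------------------------------------

class ExclusionZone:
    """A forbidden sub-volume; implements a vectorized membership test."""

    def contains(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class TubeExclusion(ExclusionZone):
    """Cylinder parallel to the Y (anterior–posterior) axis.

    ``center_xz`` is the (x, z) axis position in µm; the tube spans
    ``y_range`` (inclusive; defaults to all Y).
    """

    center_xz: tuple
    radius_um: float
    y_range: Optional[tuple] = None

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        dx = points[:, 0] - self.center_xz[0]
        dz = points[:, 2] - self.center_xz[1]
        inside = dx * dx + dz * dz <= self.radius_um**2
        if self.y_range is not None:
            inside &= (points[:, 1] >= self.y_range[0]) & (points[:, 1] <= self.y_range[1])
        return inside


@dataclass
class VoxelExclusion(ExclusionZone):
    """Boolean voxel mask with physical geometry (µm)."""

    mask: np.ndarray  # (nx, ny, nz) boolean
    voxel_size_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        idx = np.floor((points - self.origin_um) / self.voxel_size_um).astype(int)
        inb = np.all((idx >= 0) & (idx < np.array(self.mask.shape)), axis=1)
        out = np.zeros(points.shape[0], dtype=bool)
        if inb.any():
            ii = idx[inb]
            out[inb] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_um**3 / UM3_PER_MM3

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_mm3


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

class Region3D:
    """Abstract bounded 3D domain.  Boundary points count as inside."""

    name: str = ""
    exclusion_zones: list
    #: True on subclasses whose boundary_clearance is a cheap closed form
    #: (safe to call per evaluation point in kernel estimates)
    fast_clearance: bool = False

    def __init__(self, name: str = "", exclusion_zones: Optional[list] = None):
        self.name = name
        self.exclusion_zones = list(exclusion_zones or [])

    # -- contract -----------------------------------------------------------
    @property
    def volume_mm3(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def bounding_box(self) -> tuple:
        """(lo, hi) corners in µm, each a length-3 array."""
        raise NotImplementedError  # pragma: no cover

    def _contains_boundary(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover

    # -- shared behaviour ---------------------------------------------------
    def contains(self, points: np.ndarray, honor_exclusions: bool = False) -> np.ndarray:
        """Vectorized membership test; scalar input returns a scalar bool."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(np.isfinite(pts)):
            raise GeometryError("membership test on non-finite point")
        inside = self._contains_boundary(pts)
        if honor_exclusions:
            for zone in self.exclusion_zones:
                inside &= ~zone.contains(pts)
        if np.asarray(points).ndim == 1:
            return bool(inside[0])
        return inside

    def boundary_clearance(self, points: np.ndarray) -> np.ndarray:
        """Lower bound on distance (µm) from interior points to the boundary.

        Generic fallback probes 128 sphere directions by bisection; analytic
        subclasses override with closed forms.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo_c, hi_c = self.bounding_box()
        rmax = float(np.linalg.norm(hi_c - lo_c))
        dirs = _fibonacci_sphere(128)
        out = np.zeros(pts.shape[0])
        for i, p in enumerate(pts):
            if not self.contains(p):
                out[i] = 0.0
                continue
            lo, hi = 0.0, rmax
            for _ in range(24):
                mid = 0.5 * (lo + hi)
                if np.all(self.contains(p + mid * dirs)):
                    lo = mid
                else:
                    hi = mid
            out[i] = lo
        return out

    def exclusion_fraction(self, n_probe: int = 200_000, seed: int = 0) -> float:
        """Monte Carlo estimate of the volume fraction occupied by exclusions."""
        if not self.exclusion_zones:
            return 0.0
        rng = np.random.default_rng(seed)
        pts = self._mc_points_inside(n_probe, rng)
        if pts.shape[0] == 0:
            return 0.0
        excluded = np.zeros(pts.shape[0], dtype=bool)
        for zone in self.exclusion_zones:
            excluded |= zone.contains(pts)
        return float(excluded.mean())

    def _mc_points_inside(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounding_box()
        pts = rng.uniform(lo, hi, size=(n, 3))
        return pts[self._contains_boundary(pts)]

    def clipped_volume_below_y(self, y_um: float, n_probe: int = 400_000) -> float:
        """Volume (mm³) of the part of the region with Y ≤ y_um.

        Generic Monte Carlo estimate with a fixed internal stream; analytic
        subclasses override exactly.
        """
        rng = np.random.default_rng(1234567)
        pts = self._mc_points_inside(n_probe, rng)
        if pts.shape[0] == 0:
            return 0.0
        return float((pts[:, 1] <= y_um).mean()) * self.volume_mm3

    def y_median_plane(self) -> float:
        """Y value splitting the region into two equal sub-volumes."""
        lo, hi = self.bounding_box()
        target = 0.5 * self.volume_mm3
        a, b = float(lo[1]), float(hi[1])
        for _ in range(60):
            mid = 0.5 * (a + b)
            if self.clipped_volume_below_y(mid) < target:
                a = mid
            else:
                b = mid
        return 0.5 * (a + b)


class BoxRegion(Region3D):
    """Axis-aligned box [lo, hi] in µm."""

    fast_clearance = True

    def __init__(self, lo, hi, name: str = "box", exclusion_zones=None):
        super().__init__(name, exclusion_zones)
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        if np.any(self.hi <= self.lo):
            raise GeometryError("box must have positive extent on every axis")

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.hi - self.lo)) / UM3_PER_MM3

    def bounding_box(self):
        return self.lo.copy(), self.hi.copy()

    def _contains_boundary(self, pts):
        return np.all((pts >= self.lo) & (pts <= self.hi), axis=1)

    def boundary_clearance(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.minimum(pts - self.lo, self.hi - pts).min(axis=1)
        return np.clip(d, 0.0, None)

    def clipped_volume_below_y(self, y_um, n_probe=None):
        frac = np.clip((y_um - self.lo[1]) / (self.hi[1] - self.lo[1]), 0.0, 1.0)
        return float(frac) * self.volume_mm3


class BallRegion(Region3D):
    """Ball of given radius (µm)."""

    fast_clearance = True

    def __init__(self, center, radius_um, name: str = "ball", exclusion_zones=None):
        super().__init__(name, exclusion_zones)
        self.center = np.asarray(center, dtype=float)
        self.radius_um = float(radius_um)
        if self.radius_um <= 0:
            raise GeometryError("ball radius must be positive")

    @property
    def volume_mm3(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius_um**3 / UM3_PER_MM3

    def bounding_box(self):
        r = self.radius_um
        return self.center - r, self.center + r

    def _contains_boundary(self, pts):
        return np.linalg.norm(pts - self.center, axis=1) <= self.radius_um

    def boundary_clearance(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.radius_um - np.linalg.norm(pts - self.center, axis=1)
        return np.clip(d, 0.0, None)

    def clipped_volume_below_y(self, y_um, n_probe=None):
        u = np.clip((y_um - self.center[1]) / self.radius_um, -1.0, 1.0)
        frac = (2.0 + 3.0 * u - u**3) / 4.0
        return float(frac) * self.volume_mm3


class EllipsoidRegion(Region3D):
    """Axis-aligned ellipsoid with semi-axes (a, b, c) µm along (X, Y, Z)."""

    fast_clearance = True

    def __init__(self, center, semi_axes_um, name: str = "ellipsoid", exclusion_zones=None):
        super().__init__(name, exclusion_zones)
        self.center = np.asarray(center, dtype=float)
        self.semi_axes_um = np.asarray(semi_axes_um, dtype=float)
        if np.any(self.semi_axes_um <= 0):
            raise GeometryError("ellipsoid semi-axes must be positive")

    @property
    def volume_mm3(self) -> float:
        return (4.0 / 3.0) * np.pi * float(np.prod(self.semi_axes_um)) / UM3_PER_MM3

    def bounding_box(self):
        return self.center - self.semi_axes_um, self.center + self.semi_axes_um

    def _contains_boundary(self, pts):
        q = ((pts - self.center) / self.semi_axes_um) ** 2
        return q.sum(axis=1) <= 1.0 + 1e-12

    def boundary_clearance(self, points):
        # (1 - m) * min(semi-axes) is a valid lower bound on the distance
        # from a point with scaled radius m < 1 to the ellipsoid surface.
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = np.sqrt((((pts - self.center) / self.semi_axes_um) ** 2).sum(axis=1))
        return np.clip((1.0 - m) * self.semi_axes_um.min(), 0.0, None)

    def clipped_volume_below_y(self, y_um, n_probe=None):
        u = np.clip((y_um - self.center[1]) / self.semi_axes_um[1], -1.0, 1.0)
        frac = (2.0 + 3.0 * u - u**3) / 4.0
        return float(frac) * self.volume_mm3


class MeshRegion(Region3D):
    """Tetrahedral complex: convex hull or alpha complex of a point cloud.

    Stores the Delaunay tetrahedralization and a keep-mask of tetrahedra; the
    boundary surface is the set of triangles incident to exactly one kept
    tetrahedron.  Membership = falling inside a kept tetrahedron.
    """

    def __init__(self, points, keep_mask, delaunay, name="mesh", exclusion_zones=None):
        super().__init__(name, exclusion_zones)
        self.points = np.asarray(points, dtype=float)
        self.delaunay = delaunay
        self.keep_mask = np.asarray(keep_mask, dtype=bool)
        if not self.keep_mask.any():
            raise GeometryError("alpha too small: no tetrahedron survives")
        tets = self.points[self.delaunay.simplices[self.keep_mask]]
        self._volume_um3 = float(np.abs(_tet_volumes(tets)).sum())

    @property
    def volume_mm3(self) -> float:
        return self._volume_um3 / UM3_PER_MM3

    def bounding_box(self):
        return self.points.min(axis=0), self.points.max(axis=0)

    def _contains_boundary(self, pts):
        simp = self.delaunay.find_simplex(pts, tol=1e-8)
        inside = simp >= 0
        inside[inside] = self.keep_mask[simp[inside]]
        return inside

    def boundary_surface(self):
        """(vertices, faces) of the boundary triangulation."""
        from collections import Counter

        counts = Counter()
        for tet in self.delaunay.simplices[self.keep_mask]:
            for face in _tet_faces(tet):
                counts[face] += 1
        faces = np.array([f for f, c in counts.items() if c == 1], dtype=int)
        return self.points, faces


class VoxelRegion(Region3D):
    """Boolean voxel grid with physical geometry."""

    def __init__(self, mask, voxel_size_um, origin_um=(0, 0, 0), name="voxels",
                 exclusion_zones=None):
        super().__init__(name, exclusion_zones)
        self.mask = np.asarray(mask, dtype=bool)
        self.voxel_size_um = float(voxel_size_um)
        self.origin_um = np.asarray(origin_um, dtype=float)
        if self.mask.ndim != 3:
            raise GeometryError("voxel mask must be 3D")

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_size_um**3 / UM3_PER_MM3

    def bounding_box(self):
        lo = self.origin_um
        hi = self.origin_um + np.array(self.mask.shape) * self.voxel_size_um
        return lo.copy(), hi

    def _contains_boundary(self, pts):
        idx = np.floor((pts - self.origin_um) / self.voxel_size_um).astype(int)
        inb = np.all((idx >= 0) & (idx < np.array(self.mask.shape)), axis=1)
        out = np.zeros(pts.shape[0], dtype=bool)
        if inb.any():
            ii = idx[inb]
            out[inb] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def voxel_centers(self) -> np.ndarray:
        """Physical centers (µm) of the True voxels."""
        idx = np.argwhere(self.mask)
        return self.origin_um + (idx + 0.5) * self.voxel_size_um


# ---------------------------------------------------------------------------
# Construction and measurement
# ---------------------------------------------------------------------------

def build_region(points, alpha_um=np.inf, name: str = "region") -> MeshRegion:
    """Region boundary from soma coordinates: convex hull or alpha complex.

    With ``alpha_um = inf`` the result is the convex hull.  For finite alpha
    only Delaunay tetrahedra with circumradius ≤ alpha are kept (the alpha
    complex), which generalizes the hull to non-convex outlines.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.shape[0] < 4:
        raise GeometryError("need at least 4 points to build a 3D region")
    try:
        tri = Delaunay(points)
    except Exception as exc:  # qhull error on degenerate input
        raise GeometryError(f"degenerate point configuration: {exc}") from exc
    if tri.simplices.shape[0] == 0:
        raise GeometryError("degenerate (coplanar) point configuration")
    tets = points[tri.simplices]
    vols = np.abs(_tet_volumes(tets))
    if np.all(vols < 1e-12):
        raise GeometryError("degenerate (coplanar) point configuration")
    if np.isinf(alpha_um):
        keep = vols > 0
    else:
        if alpha_um <= 0:
            raise GeometryError("alpha must be positive or infinite")
        keep = (vols > 0) & (_circumradii(tets) <= alpha_um)
        if not keep.any():
            raise GeometryError("alpha too small: no tetrahedron survives")
    return MeshRegion(points, keep, tri, name=name)


def region_volume(region: Region3D, exclude_exclusions: bool = False) -> float:
    """Volume in mm³; optionally net of exclusion-zone volume.

    The default includes exclusion zones (bundles) in the region volume,
    matching how structural volumes are reported.
    """
    vol = region.volume_mm3
    if vol <= 0:
        raise GeometryError("region has non-positive volume")
    if exclude_exclusions and region.exclusion_zones:
        vol *= 1.0 - region.exclusion_fraction()
    return vol


def sample_uniform(region: Region3D, n: int, honor_exclusions: bool = False,
                   seed=None, rng: Optional[np.random.Generator] = None,
                   max_proposals: int = 50_000_000) -> PointPattern3D:
    """Exactly ``n`` points uniform in the admissible part of the region.

    Rejection sampling from the bounding box, deterministic for a given seed.
    Errors out if the admissible volume fraction appears to be below 1e-6 of
    the bounding box (to guarantee termination).
    """
    if n < 0:
        raise GeometryError("n must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = region.bounding_box()
    out = np.empty((0, 3))
    proposed = 0
    batch = max(4096, 2 * n)
    while out.shape[0] < n:
        pts = rng.uniform(lo, hi, size=(batch, 3))
        proposed += batch
        keep = region.contains(pts, honor_exclusions=honor_exclusions)
        out = np.vstack([out, pts[keep]])
        if proposed > 1_000_000 and out.shape[0] < proposed * 1e-6:
            raise GeometryError("admissible volume fraction below 1e-6; aborting")
        if proposed > max_proposals:
            raise GeometryError("rejection sampling exceeded proposal budget")
    return PointPattern3D(out[:n], region=np.full(n, region.name, dtype=object))


def extract_ball_subregion(pattern: PointPattern3D, region: Region3D,
                           radius_um: float, center="auto",
                           grid_um: float = 100.0):
    """Points inside an interior ball, plus the spherical subregion.

    Used to reduce edge effects on local-density analyses: the ball must fit
    entirely inside the region.  ``center='auto'`` picks the grid point
    (spacing ``grid_um``) with maximal boundary clearance.
    """
    if center == "auto":
        lo, hi = region.bounding_box()

        def _axes(g):
            # nodes at integer multiples of g from the box corner, so the
            # box/ellipsoid midplanes fall on the grid
            return [np.arange(l + g, h, g) for l, h in zip(lo, hi)]

        axes = _axes(grid_um)
        # cap the grid so mesh/voxel clearance probing stays tractable
        while np.prod([len(a) for a in axes]) > 40_000:
            grid_um *= 1.5
            axes = _axes(grid_um)
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        cand = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        cand = cand[region.contains(cand)]
        if cand.shape[0] == 0:
            raise GeometryError("no interior grid point found")
        clear = region.boundary_clearance(cand)
        best = int(np.argmax(clear))
        if clear[best] < radius_um:
            raise GeometryError(
                f"no placement: max clearance {clear[best]:.1f} µm < radius {radius_um} µm"
            )
        center = cand[best]
    else:
        center = np.asarray(center, dtype=float)
        if float(region.boundary_clearance(center[None, :])[0]) < radius_um * (1 - 1e-9):
            raise GeometryError("ball does not fit inside the region at given center")
    ball = BallRegion(center, radius_um, name=f"{region.name}_ball")
    mask = np.linalg.norm(pattern.coords - center, axis=1) <= radius_um
    return pattern.subset(mask), ball


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _tet_volumes(tets: np.ndarray) -> np.ndarray:
    """Signed volumes of an (m, 4, 3) array of tetrahedra."""
    a = tets[:, 1] - tets[:, 0]
    b = tets[:, 2] - tets[:, 0]
    c = tets[:, 3] - tets[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _circumradii(tets: np.ndarray) -> np.ndarray:
    """Circumsphere radii of an (m, 4, 3) array of tetrahedra."""
    p0 = tets[:, 0]
    rel = tets[:, 1:] - p0[:, None, :]          # (m, 3, 3)
    sq = (rel**2).sum(axis=2)                    # (m, 3)
    m = tets.shape[0]
    radii = np.full(m, np.inf)
    det = np.linalg.det(rel)
    ok = np.abs(det) > 1e-9
    if ok.any():
        centers = np.linalg.solve(rel[ok], 0.5 * sq[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def _tet_faces(tet):
    i, j, k, l = (int(v) for v in tet)
    return (tuple(sorted((i, j, k))), tuple(sorted((i, j, l))),
            tuple(sorted((i, k, l))), tuple(sorted((j, k, l))))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5)) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)
    ])
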