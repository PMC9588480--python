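"""3D Voronoi tessellation of soma centroids with region-clipped cell
volumes.

Each generator point owns the part of space closer to it than to any other
generator; cell volume measures the "territory" around each soma.  Cells of
boundary-adjacent generators are unbounded and must either be intersected
with the region (mode "clip", conserving total volume) or dropped from
summaries (mode "interior_only").  Clipping is exact (halfspace
intersection) for box and convex-hull regions and voxel-based for arbitrary
region shapes; the voxel route doubles as an independent oracle for the
exact one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError, Voronoi, cKDTree

from .geometry import BoxRegion, MeshRegion, PointPattern3D, Region3D

UM3_PER_MM3 = 1e9


@dataclass
class VoronoiResult:
    volumes_mm3: np.ndarray        # per generator; NaN = excluded (interior_only)
    clipped: np.ndarray            # True where the cell touches the boundary
    region_volume_mm3: float
    mode: str

    @property
    def valid_volumes(self) -> np.ndarray:
        v = self.volumes_mm3
        return v[np.isfinite(v)]

    @property
    def mean_mm3(self) -> float:
        return float(self.valid_volumes.mean())

    @property
    def sd_mm3(self) -> float:
        return float(self.valid_volumes.std(ddof=1))


def _region_halfspaces(region: Region3D) -> Optional[np.ndarray]:
    """Region as convex halfspaces [A | b] with A·x + b ≤ 0, or None."""
    if isinstance(region, BoxRegion):
        hs = []
        for ax in range(3):
            for sign, bound in ((-1.0, region.lo[ax]), (1.0, region.hi[ax])):
                a = np.zeros(3)
                a[ax] = sign
                hs.append(np.append(a, -sign * bound))
        return np.array(hs)
    if isinstance(region, MeshRegion) and region.keep_mask.all():
        hull = ConvexHull(region.points)
        return hull.equations  # already A·x + b <= 0 for interior
    return None


def voronoi_volumes(pattern: PointPattern3D, region: Region3D,
                    mode: str = "clip", voxel_size_um: float = 20.0,
                    jitter_um: float = 0.0) -> VoronoiResult:
    """Voronoi cell volumes for all generators.

    mode "clip": each cell intersected with the region; volumes conserve the
    region volume.  mode "interior_only": cells touching the boundary are
    excluded (NaN) from volumes and summaries.  ``jitter_um`` perturbs
    degenerate (coplanar/cocircular) configurations deterministically.
    """
    if pattern.n < 5:
        raise ValueError("need at least 5 generators")
    coords = pattern.coords
    if jitter_um > 0:
        coords = coords + np.random.default_rng(20240107).normal(
            0.0, jitter_um, size=coords.shape)
    try:
        if mode == "clip":
            hs = _region_halfspaces(region)
            if hs is not None:
                vols = _clip_exact(coords, hs)
                clipped = _boundary_flags(coords, region)
            else:
                vols, clipped = _clip_voxel(coords, region, voxel_size_um)
            return VoronoiResult(vols, clipped, region.volume_mm3, mode)
        if mode == "interior_only":
            vols, clipped = _interior_only(coords, region)
            return VoronoiResult(vols, clipped, region.volume_mm3, mode)
    except QhullError as exc:
        raise ValueError(
            f"degenerate generator configuration (try jitter_um > 0): {exc}"
        ) from exc
    raise ValueError(f"unknown mode {mode!r}")


def _clip_exact(coords: np.ndarray, region_hs: np.ndarray) -> np.ndarray:
    """Halfspace-intersection volumes of every cell, clipped to a convex
    region given as halfspaces."""
    n = coords.shape[0]
    vols = np.empty(n)
    interior = coords.mean(axis=0)
    scale = np.linalg.norm(coords.max(axis=0) - coords.min(axis=0))
    for i in range(n):
        diffs = coords - coords[i]                      # (n, 3)
        mids = 0.5 * (coords + coords[i])
        keep = np.arange(n) != i
        a = diffs[keep]
        b = -np.einsum("ij,ij->i", a, mids[keep])
        hs = np.vstack([np.column_stack([a, b]), region_hs])
        # generators on the region boundary are not strictly feasible for
        # qhull; nudge the feasible point slightly inward (stays inside the
        # cell unless another generator is within the nudge distance)
        last = None
        for eps in (0.0, 1e-9, 1e-6):
            feas = coords[i] + eps * (interior - coords[i])
            try:
                inter = HalfspaceIntersection(hs, feas)
                vols[i] = ConvexHull(inter.intersections).volume / UM3_PER_MM3
                last = None
                break
            except QhullError as exc:
                last = exc
        if last is not None:
            raise ValueError(
                f"degenerate configuration at generator {i} "
                f"(try jitter_um > 0): {last}"
            ) from last
    return vols


def _boundary_flags(coords: np.ndarray, region: Region3D) -> np.ndarray:
    """Mark generators whose unclipped Voronoi cell leaves the region."""
    vor = Voronoi(coords)
    flags = np.zeros(coords.shape[0], dtype=bool)
    for i, reg_idx in enumerate(vor.point_region):
        verts = vor.regions[reg_idx]
        if -1 in verts:
            flags[i] = True
            continue
        if not np.all(region.contains(vor.vertices[verts])):
            flags[i] = True
    return flags


def _voxel_assignment(coords: np.ndarray, region: Region3D,
                      voxel_size_um: float):
    """Nearest-generator labels on a voxel grid covering the region."""
    lo, hi = region.bounding_box()
    shape = np.maximum(np.ceil((hi - lo) / voxel_size_um).astype(int), 1)
    axes = [lo[ax] + (np.arange(shape[ax]) + 0.5) * voxel_size_um
            for ax in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = region.contains(centers).reshape(shape)
    tree = cKDTree(coords)
    labels = np.full(shape, -1, dtype=int)
    _, owner = tree.query(centers[inside.ravel()])
    labels[inside] = owner
    return labels, inside, voxel_size_um


def _clip_voxel(coords: np.ndarray, region: Region3D, voxel_size_um: float):
    labels, inside, vs = _voxel_assignment(coords, region, voxel_size_um)
    n = coords.shape[0]
    counts = np.bincount(labels[inside].ravel(), minlength=n)
    vols = counts * vs**3 / UM3_PER_MM3
    # boundary voxels = inside voxels with an outside 6-neighbor
    eroded = ndimage.binary_erosion(inside)
    boundary_owner = labels[inside & ~eroded]
    clipped = np.zeros(n, dtype=bool)
    clipped[np.unique(boundary_owner)] = True
    return vols, clipped


def _interior_only(coords: np.ndarray, region: Region3D):
    vor = Voronoi(coords)
    n = coords.shape[0]
    vols = np.full(n, np.nan)
    clipped = np.ones(n, dtype=bool)
    for i, reg_idx in enumerate(vor.point_region):
        verts = vor.regions[reg_idx]
        if -1 in verts or len(verts) == 0:
            continue
        vv = vor.vertices[verts]
        if not np.all(region.contains(vv)):
            continue
        clipped[i] = False
        vols[i] = ConvexHull(vv).volume / UM3_PER_MM3
    return vols, clipped


def voxel_oracle_volumes(pattern: PointPattern3D, region: Region3D,
                         voxel_size_um: float = 10.0) -> np.ndarray:
    """Brute-force nearest-generator voxel volumes (independent oracle)."""
    labels, inside, vs = _voxel_assignment(pattern.coords, region, voxel_size_um)
    counts = np.bincount(labels[inside].ravel(), minlength=pattern.n)
    return counts * vs**3 / UM3_PER_MM3


def voronoi_histogram(result: VoronoiResult, bins=20):
    """Frequency distribution of inter-neuronal (cell) volumes plus
    mean ± SD in mm³."""
    vols = result.valid_volumes
    if vols.size == 0:
        raise ValueError("no cell volumes to histogram")
    if np.ptp(vols) <= 1e-9 * np.abs(vols).max():  # all (nearly) equal
        span = (vols[0] * 0.999, vols[0] * 1.001 + 1e-300)
        freq, edges = np.histogram(vols, bins=1, range=span)
    else:
        freq, edges = np.histogram(vols, bins=bins)
    sd = float(vols.std(ddof=1)) if vols.size > 1 else 0.0
    return dict(frequencies=freq, bin_edges=edges,
                mean_mm3=float(vols.mean()), sd_mm3=sd, n=int(vols.size))
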