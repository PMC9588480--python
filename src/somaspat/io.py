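"""Readers/writers for coordinate tables, exclusion masks, region meshes and
configs, plus the end-to-end pipeline orchestrator.

The native coordinate format is CSV with columns
``x_um, y_um, z_um, region, hemisphere[, diameter_um]``; XLSX is accepted for
externally supplied coordinate databases, with header synonym sniffing
(x/y/z, structure/nucleus for region, side for hemisphere, size/somal size
for diameter).  Voxel masks travel as boolean multi-page TIFF or voxel-list
CSV, each with a JSON sidecar giving voxel size (µm) and origin.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import inhomogeneous as _inhom
from . import neighbors as _neighbors
from . import ripley as _ripley
from . import synthetic as _synthetic
from . import tessellation as _tess
from .density import anterior_posterior_f_test, hemispheric_summary
from .geometry import (
    GeometryError,
    PointPattern3D,
    Region3D,
    VoxelExclusion,
)

KNOWN_REGIONS = set(_synthetic.REGION_NAMES)

_COLUMN_SYNONYMS = {
    "x_um": {"x_um", "x", "x (um)", "x(um)", "x [um]"},
    "y_um": {"y_um", "y", "y (um)", "y(um)", "y [um]"},
    "z_um": {"z_um", "z", "z (um)", "z(um)", "z [um]"},
    "region": {"region", "structure", "nucleus", "area", "region_label"},
    "hemisphere": {"hemisphere", "hemi", "side"},
    "diameter_um": {"diameter_um", "diameter", "size", "somal_size",
                    "somal size", "soma_diameter"},
}


class SchemaError(ValueError):
    """Malformed coordinate table or mask file."""


def _map_columns(columns):
    mapping = {}
    lower = {str(c).strip().lower(): c for c in columns}
    for canonical, names in _COLUMN_SYNONYMS.items():
        for name in names:
            if name in lower:
                mapping[canonical] = lower[name]
                break
    return mapping


def read_coordinates(path, permissive: bool = False) -> PointPattern3D:
    """Load a soma coordinate table (CSV or XLSX) into a point pattern.

    Header synonyms are sniffed; unknown region labels are rejected unless
    ``permissive``.  Row order is preserved.
    """
    path = Path(path)
    # keep_default_na=False: the region label "NA" (nucleus accumbens) must
    # not be read as a missing value
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path, keep_default_na=False)
        else:
            df = pd.read_csv(path, keep_default_na=False,
                             float_precision="round_trip")
    except (pd.errors.EmptyDataError, ValueError) as exc:
        raise SchemaError(f"{path}: unreadable coordinate table: {exc}") from exc
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: empty coordinate table")
    mapping = _map_columns(df.columns)
    missing = [c for c in ("x_um", "y_um", "z_um") if c not in mapping]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    coords = np.empty((df.shape[0], 3))
    for j, axis in enumerate(("x_um", "y_um", "z_um")):
        col = pd.to_numeric(df[mapping[axis]], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(col.to_numpy(dtype=float)))
        if bad.size:
            raise SchemaError(
                f"{path}: non-numeric {axis} at data row(s) {bad[:5].tolist()}")
        coords[:, j] = col.to_numpy(dtype=float)
    region = hemisphere = diameter = None
    if "region" in mapping:
        region = df[mapping["region"]].astype(str).to_numpy(dtype=object)
        unknown = sorted(set(region) - KNOWN_REGIONS)
        if unknown and not permissive:
            raise SchemaError(
                f"{path}: unknown region label(s) {unknown}; "
                f"pass permissive=True to accept")
    if "hemisphere" in mapping:
        hemisphere = df[mapping["hemisphere"]].astype(str).to_numpy(dtype=object)
    if "diameter_um" in mapping:
        diameter = pd.to_numeric(df[mapping["diameter_um"]],
                                 errors="coerce").to_numpy(dtype=float)
    return PointPattern3D(coords, region, hemisphere, diameter)


def write_coordinates(pattern: PointPattern3D, path) -> None:
    """Write a pattern as the native CSV schema (full float precision)."""
    data = {"x_um": pattern.coords[:, 0], "y_um": pattern.coords[:, 1],
            "z_um": pattern.coords[:, 2]}
    if pattern.region is not None:
        data["region"] = pattern.region
    if pattern.hemisphere is not None:
        data["hemisphere"] = pattern.hemisphere
    if pattern.diameter_um is not None:
        data["diameter_um"] = pattern.diameter_um
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Exclusion masks
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mask(mask: VoxelExclusion, path) -> None:
    """Boolean mask as multi-page TIFF (or voxel-list CSV for .csv paths)
    with a JSON geometry sidecar."""
    path = Path(path)
    meta = dict(voxel_size_um=mask.voxel_size_um,
                origin_um=mask.origin_um.tolist(),
                shape=list(mask.mask.shape))
    if path.suffix.lower() == ".csv":
        idx = np.argwhere(mask.mask)
        pd.DataFrame(idx, columns=["ix", "iy", "iz"]).to_csv(path, index=False)
    else:
        import tifffile
        # pages along the first (X) axis
        tifffile.imwrite(path, mask.mask.astype(np.uint8))
    _sidecar_path(path).write_text(json.dumps(meta))


def read_mask(path) -> VoxelExclusion:
    """Load an exclusion mask (TIFF stack or voxel-list CSV) + sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"missing geometry sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("voxel_size_um", "origin_um", "shape"):
        if key not in meta:
            raise SchemaError(f"{sidecar}: missing key {key!r}")
    shape = tuple(meta["shape"])
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        mask = np.zeros(shape, dtype=bool)
        if df.shape[0]:
            idx = df[["ix", "iy", "iz"]].to_numpy(dtype=int)
            if np.any(idx < 0) or np.any(idx >= np.array(shape)):
                raise SchemaError(f"{path}: voxel index outside declared shape")
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    else:
        import tifffile
        mask = tifffile.imread(path).astype(bool)
        if mask.shape != shape:
            raise SchemaError(
                f"{path}: TIFF shape {mask.shape} != sidecar shape {shape}")
    return VoxelExclusion(mask, float(meta["voxel_size_um"]),
                          np.asarray(meta["origin_um"], dtype=float))


def tubes_to_voxel_mask(tubes, region: Region3D,
                        voxel_size_um: float = 50.0) -> VoxelExclusion:
    """Rasterize analytic tube exclusions onto a voxel grid covering the
    region's bounding box (voxels outside the region stay False)."""
    lo, hi = region.bounding_box()
    shape = np.maximum(np.ceil((hi - lo) / voxel_size_um).astype(int), 1)
    axes = [lo[ax] + (np.arange(shape[ax]) + 0.5) * voxel_size_um
            for ax in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = region.contains(centers)
    hit = np.zeros(centers.shape[0], dtype=bool)
    for tube in tubes:
        hit |= tube.contains(centers)
    return VoxelExclusion((hit & inside).reshape(shape), voxel_size_um, lo)


def mask_occupancy(mask: VoxelExclusion, region: Region3D,
                   n_probe: int = 120_000, seed: int = 0) -> float:
    """Fraction of the region volume covered by the mask (Monte Carlo).
    Errors if the mask extent does not overlap the region."""
    m_lo = mask.origin_um
    m_hi = mask.origin_um + np.array(mask.mask.shape) * mask.voxel_size_um
    r_lo, r_hi = region.bounding_box()
    if np.any(m_hi < r_lo) or np.any(m_lo > r_hi):
        raise SchemaError("mask extent does not overlap the region")
    rng = np.random.default_rng(seed)
    pts = region._mc_points_inside(n_probe, rng)
    if pts.shape[0] == 0:
        raise GeometryError("region admits no probe points")
    return float(mask.contains(pts).mean())


# ---------------------------------------------------------------------------
# Region mesh I/O (OFF / PLY, ASCII) via trimesh
# ---------------------------------------------------------------------------

def _winding_numbers(vertices, faces, pts, chunk=256):
    """Generalized winding number of each point w.r.t. a closed triangulated
    surface (van Oosterom–Strackee solid angles; 1 inside, 0 outside)."""
    tri = vertices[faces]  # (m, 3, 3)
    out = np.empty(pts.shape[0])
    for i in range(0, pts.shape[0], chunk):
        p = pts[i:i + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("pmi,pmi->pm", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("pmi,pmi->pm", a, b) * lc
               + np.einsum("pmi,pmi->pm", b, c) * la
               + np.einsum("pmi,pmi->pm", a, c) * lb)
        out[i:i + chunk] = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
    return out


class FileMeshRegion(Region3D):
    """Region backed by a watertight triangulated surface loaded from file.

    Membership uses the generalized winding number of the closed surface
    (≈1 inside, ≈0 outside; near-surface points count as inside).
    """

    def __init__(self, mesh, name="mesh_file", exclusion_zones=None):
        super().__init__(name, exclusion_zones)
        if not mesh.is_watertight:
            raise GeometryError("mesh is not watertight (open surface)")
        self.mesh = mesh

    @property
    def volume_mm3(self) -> float:
        return float(abs(self.mesh.volume)) / 1e9

    def bounding_box(self):
        return (np.asarray(self.mesh.bounds[0], dtype=float),
                np.asarray(self.mesh.bounds[1], dtype=float))

    def _contains_boundary(self, pts):
        w = _winding_numbers(np.asarray(self.mesh.vertices, dtype=float),
                             np.asarray(self.mesh.faces, dtype=int), pts)
        return np.abs(w) >= 0.5


def write_region_mesh(region, path) -> None:
    """Export a tetra-complex region boundary as ASCII OFF or PLY."""
    import trimesh
    verts, faces = region.boundary_surface()
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    mesh.export(path)


def read_region_mesh(path, name=None) -> FileMeshRegion:
    import trimesh
    mesh = trimesh.load_mesh(path)
    return FileMeshRegion(mesh, name=name or Path(path).stem)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Everything the end-to-end pipeline needs; YAML round-trip stable."""

    out_dir: str = "results/pipeline"
    coords_path: Optional[str] = None      # None -> simulate the fixture set
    seed: int = 17
    n_sims: int = 1000                     # CSR envelope simulations
    n_null: int = 99                       # inhomogeneous-Poisson nulls
    n_radii: int = 100
    alpha_um: Optional[float] = None       # None/inf -> convex hull (file data)
    bandwidth: str | float = "silverman"
    ball_radius_um: float = 1000.0
    split_plane: str | float = "median"
    honor_exclusions: bool = True
    use_ball_subregion: bool = True
    with_bundles: bool = True
    voronoi_voxel_um: float = 50.0
    nn_k: int = 10

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run summaries → K envelopes → homogeneity → K_inhom → NN/clusters →
    Voronoi for every structure × hemisphere; write TSVs and a manifest.

    Deterministic for a given config + seed.  Returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("simulate", "ripley", "inhom", "nn"), master.spawn(4))}
    manifest = dict(config=asdict(config), stages={}, regions=[],
                    versions=dict(python=platform.python_version(),
                                  numpy=np.__version__))

    # --- data ------------------------------------------------------------
    if config.coords_path is None:
        pattern = _synthetic.generate_bilateral_dataset(
            seeds["simulate"], with_bundles=config.with_bundles)
        write_coordinates(pattern, out / "coords.csv")
    else:
        pattern = read_coordinates(config.coords_path)
    if pattern.region is None or pattern.hemisphere is None:
        raise SchemaError("pipeline requires region and hemisphere labels")

    groups = {}
    for name in sorted(set(pattern.region)):
        for hemi in sorted(set(pattern.hemisphere)):
            mask = (pattern.region == name) & (pattern.hemisphere == hemi)
            if mask.any():
                groups[(name, hemi)] = pattern.subset(mask)
    manifest["regions"] = [f"{n}_{h}" for n, h in groups]
    manifest["total_count"] = int(pattern.n)

    def region_for(name, hemi, pat):
        if config.coords_path is None and name in _synthetic.REGION_TABLE:
            reg = _synthetic.make_region_fixture(name, hemi)
        else:
            from .geometry import build_region
            reg = build_region(pat.coords,
                               np.inf if config.alpha_um in (None, 0)
                               else config.alpha_um,
                               name=f"{name}_{hemi}")
        return reg

    regions = {key: region_for(*key, pat) for key, pat in groups.items()}

    # --- stage: density summaries ---------------------------------------
    stage = "summary"
    counts = {}
    volumes = {}
    for name in {k[0] for k in groups}:
        counts[name] = tuple(groups.get((name, h), PointPattern3D(np.empty((0, 3)))).n
                             for h in ("L", "R"))
        volumes[name] = tuple(regions[(name, h)].volume_mm3
                              if (name, h) in regions else np.nan
                              for h in ("L", "R"))
    summary = hemispheric_summary(counts, volumes)
    summary.table.to_csv(out / "table_density.tsv", sep="\t")
    manifest["stages"][stage] = "ok"
    manifest["count_difference"] = summary.count_difference

    # --- stage: homogeneity F-tests --------------------------------------
    rows = []
    for (name, hemi), pat in groups.items():
        res = anterior_posterior_f_test(pat, regions[(name, hemi)],
                                        plane=config.split_plane)
        rows.append(dict(region=name, hemisphere=hemi, F=res.F,
                         df1=res.df[0], df2=res.df[1],
                         p_one_sided=res.p_one_sided,
                         p_two_sided=res.p_two_sided))
    pd.DataFrame(rows).to_csv(out / "table_homogeneity.tsv", sep="\t",
                              index=False)
    manifest["stages"]["homogeneity"] = "ok"

    # --- stage: Ripley K + CSR envelopes ----------------------------------
    rip_seeds = seeds["ripley"].spawn(len(groups))
    for s, ((name, hemi), pat) in zip(rip_seeds, groups.items()):
        reg = regions[(name, hemi)]
        radii = _ripley.default_radii(reg, config.n_radii)
        env = _ripley.csr_envelope(pat, reg, n_sims=config.n_sims,
                                   honor_exclusions=config.honor_exclusions,
                                   radii=radii, seed=s)
        lo, hi = env.envelope()
        t, df, p = _ripley.paired_t_compare(env.k_observed, env.sim_mean)
        pd.DataFrame(dict(r_um=radii, k_obs=env.k_observed,
                          k_sim_mean=env.sim_mean, k_lo=lo, k_hi=hi)
                     ).to_csv(out / f"k_{name}_{hemi}.tsv", sep="\t",
                              index=False)
        manifest.setdefault("paired_t", {})[f"{name}_{hemi}"] = dict(
            t=t, df=df, p=p)
    manifest["stages"]["ripley"] = "ok"

    # --- stage: inhomogeneous K (structures with density gradients) -------
    inhom_targets = [key for key in groups if key[0] in ("CPu", "NB")]
    inh_seeds = seeds["inhom"].spawn(max(len(inhom_targets), 1))
    for s, (name, hemi) in zip(inh_seeds, inhom_targets):
        pat, reg = groups[(name, hemi)], regions[(name, hemi)]
        rep = _inhom.inhom_analysis(
            pat, reg,
            use_ball_subregion=config.use_ball_subregion and name == "CPu",
            ball_radius_um=config.ball_radius_um,
            n_null=config.n_null, bandwidth=config.bandwidth, seed=s)
        pd.DataFrame(dict(r_um=rep.radii, k_inhom_obs=rep.k_obs,
                          k_inhom_null_mean=rep.k_null.mean(axis=0))
                     ).to_csv(out / f"kinhom_{name}_{hemi}.tsv", sep="\t",
                              index=False)
        manifest.setdefault("inhom_rank_test", {})[f"{name}_{hemi}"] = dict(
            rank=rep.rank, p=rep.p_value, bandwidth_um=rep.bandwidth_um)
    manifest["stages"]["inhom"] = "ok"

    # --- stage: nearest neighbors & clusters ------------------------------
    for (name, hemi), pat in groups.items():
        if pat.n <= config.nn_k:
            continue
        graph = _neighbors.nn_graph(pat)
        knn = _neighbors.knn_distances(pat, config.nn_k)
        pd.DataFrame(dict(k=np.arange(1, config.nn_k + 1),
                          mean_um=knn.mean(axis=0),
                          sd_um=knn.std(axis=0, ddof=1),
                          se_um=knn.std(axis=0, ddof=1) / np.sqrt(pat.n))
                     ).to_csv(out / f"nn_{name}_{hemi}.tsv", sep="\t",
                              index=False)
        pd.DataFrame(sorted(graph.size_histogram.items()),
                     columns=["cluster_size", "frequency"]
                     ).to_csv(out / f"clusters_{name}_{hemi}.tsv", sep="\t",
                              index=False)
    manifest["stages"]["neighbors"] = "ok"

    # --- stage: Voronoi ----------------------------------------------------
    for (name, hemi), pat in groups.items():
        if pat.n < 5:
            continue
        res = _tess.voronoi_volumes(pat, regions[(name, hemi)], mode="clip",
                                    voxel_size_um=config.voronoi_voxel_um)
        pd.DataFrame(dict(point_id=np.arange(pat.n),
                          volume_mm3=res.volumes_mm3,
                          clipped=res.clipped.astype(int))
                     ).to_csv(out / f"voronoi_{name}_{hemi}.tsv", sep="\t",
                              index=False)
        manifest.setdefault("voronoi_mean_mm3", {})[f"{name}_{hemi}"] = \
            res.mean_mm3
    manifest["stages"]["voronoi"] = "ok"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
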