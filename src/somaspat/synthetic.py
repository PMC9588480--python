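"""Synthetic soma-coordinate fixtures with the statistical structure of the
mouse forebrain cholinergic system.

Five regions are modeled (CPu caudate-putamen, NB nucleus basalis, GP globus
pallidus, NA nucleus accumbens, S septum), each hemisphere as an axis-aligned
ellipsoid elongated 1:2:1 along the anterior–posterior (Y) axis whose volume
matches the reported structural volume.  Point generators provide complete
spatial randomness (CSR), linear anterior–posterior density gradients,
Thomas-process clustering, and tube-shaped axonal-bundle exclusion zones.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .geometry import (
    EllipsoidRegion,
    GeometryError,
    PointPattern3D,
    Region3D,
    TubeExclusion,
    concatenate_patterns,
    sample_uniform,
)

# Reported per-structure characteristics: count, structural volume (mm³) and
# mean somal diameter (µm) for each hemisphere.
REGION_TABLE = {
    #         count L, count R, vol L, vol R, mean diameter µm
    "GP":  (308, 200, 2.74, 2.07, 27.37),
    "NA":  (638, 619, 2.13, 1.78, 24.33),
    "S":   (638, 827, 0.89, 1.17, 23.60),
    "NB":  (1130, 1078, 3.37, 2.95, 26.54),
    "CPu": (4002, 4549, 15.06, 15.95, 25.32),
}

REGION_NAMES = tuple(REGION_TABLE)

#: spread of somal diameters around the per-region mean (µm); the reported
#: per-region dispersions are standard errors, so a plausible cell-to-cell
#: SD is chosen here.
DIAMETER_SD_UM = 2.0

#: fraction of CPu volume occupied by axonal bundles
BUNDLE_FRACTION = 0.268

#: default endpoint (anterior:posterior) intensity ratios for the two
#: structures with documented density gradients
GRADIENT_RATIOS = {"CPu": 2.1, "NB": 1.7}


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic region fixture."""

    name: str
    hemisphere: str = "L"
    volume_mm3: Optional[float] = None
    count: Optional[int] = None
    gradient_axis: str = "y"
    gradient_ratio: float = 1.0
    bundle_fraction: float = 0.0
    bundle_radius_um: float = 100.0
    cluster_parents: int = 0
    cluster_mean_offspring: float = 0.0
    cluster_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.volume_mm3 is not None and self.volume_mm3 <= 0:
            raise ValueError("volume must be positive")
        if self.count is not None and self.count < 0:
            raise ValueError("count must be non-negative")
        if self.gradient_ratio <= 0:
            raise ValueError("gradient ratio must be positive")
        if not (0 <= self.bundle_fraction < 1):
            raise ValueError("bundle fraction must be in [0, 1)")


def _hemisphere_offset(name: str, hemisphere: str) -> np.ndarray:
    """Deterministic non-overlapping layout: hemispheres along X (left is
    more lateral-positive in this frame), structures staggered along Z."""
    ix = list(REGION_TABLE).index(name)
    x = 20_000.0 if hemisphere == "L" else 5_000.0
    return np.array([x, 5_000.0, 8_000.0 * ix + 4_000.0])


def make_region_fixture(name: str, hemisphere: str = "L",
                        volume_mm3: Optional[float] = None) -> EllipsoidRegion:
    """Ellipsoid region fixture (semi-axes a:2a:a) with the reported volume."""
    if name not in REGION_TABLE:
        raise KeyError(f"unknown region {name!r}; expected one of {REGION_NAMES}")
    if hemisphere not in ("L", "R"):
        raise ValueError("hemisphere must be 'L' or 'R'")
    if volume_mm3 is None:
        row = REGION_TABLE[name]
        volume_mm3 = row[2] if hemisphere == "L" else row[3]
    # V = (4/3)π a · 2a · a  =>  a = (3V / 8π)^(1/3)
    a_um = (3.0 * volume_mm3 * 1e9 / (8.0 * np.pi)) ** (1.0 / 3.0)
    center = _hemisphere_offset(name, hemisphere)
    return EllipsoidRegion(center, (a_um, 2.0 * a_um, a_um),
                           name=f"{name}_{hemisphere}")


def generate_csr(region: Region3D, n: int, seed=None, rng=None,
                 honor_exclusions: bool = True) -> PointPattern3D:
    """Completely spatially random pattern of exactly ``n`` points."""
    return sample_uniform(region, n, honor_exclusions=honor_exclusions,
                          seed=seed, rng=rng)


def generate_gradient(region: Region3D, n: int, axis: str = "y",
                      ratio: float = 2.0, seed=None, rng=None,
                      honor_exclusions: bool = True) -> PointPattern3D:
    """Inhomogeneous Poisson sample with a linear intensity gradient.

    The intensity falls linearly along ``axis`` from ``ratio`` at the
    anterior extreme (low coordinate) to 1 at the posterior extreme, so
    ``ratio`` is the anterior:posterior endpoint density ratio.  Simulation
    is conditional on the total count ``n`` (thinning of uniform proposals).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    lo, hi = region.bounding_box()
    span = hi[ax] - lo[ax]
    lam_max = max(ratio, 1.0)
    coords = np.empty((0, 3))
    while coords.shape[0] < n:
        cand = sample_uniform(region, max(4 * n, 1000),
                              honor_exclusions=honor_exclusions, rng=rng).coords
        t = (cand[:, ax] - lo[ax]) / span
        lam = ratio + (1.0 - ratio) * t
        keep = rng.uniform(0, lam_max, size=cand.shape[0]) < lam
        coords = np.vstack([coords, cand[keep]])
    return PointPattern3D(coords[:n], region=np.full(n, region.name, dtype=object))


def gradient_anterior_fraction(ratio: float) -> float:
    """Expected fraction of gradient points in the anterior half-ellipsoid.

    Closed form for a linear endpoint-ratio gradient in an ellipsoid, used as
    an analytic oracle: with u the normalized axis coordinate in [-1, 1],
    cross-section weight (1 - u²) and intensity A - C·u where
    A = (ratio+1)/2, C = (ratio-1)/2, the anterior (u < 0) mass fraction is
    (2A/3 + C/4) / (4A/3).
    """
    a_coef = (ratio + 1.0) / 2.0
    c_coef = (ratio - 1.0) / 2.0
    anterior = 2.0 * a_coef / 3.0 + c_coef / 4.0
    total = 4.0 * a_coef / 3.0
    return anterior / total


def generate_thomas(region: Region3D, parent_count: int, mean_offspring: float,
                    sd_um: float, seed=None, rng=None,
                    honor_exclusions: bool = True) -> PointPattern3D:
    """Thomas cluster process conditioned on the parent count.

    Parents are uniform in the region; each gets Poisson(``mean_offspring``)
    children displaced by an isotropic Gaussian of scale ``sd_um``.  Children
    falling outside the admissible region have their displacement redrawn, so
    the realized count keeps the parents × Poisson structure.
    """
    if parent_count < 0 or mean_offspring < 0 or sd_um < 0:
        raise ValueError("Thomas parameters must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    parents = sample_uniform(region, parent_count,
                             honor_exclusions=honor_exclusions, rng=rng).coords
    counts = rng.poisson(mean_offspring, size=parent_count)
    children = []
    for p, c in zip(parents, counts):
        placed = 0
        while placed < c:
            offs = p + rng.normal(0.0, sd_um, size=(c - placed, 3)) if sd_um > 0 \
                else np.tile(p, (c - placed, 1))
            ok = region.contains(offs, honor_exclusions=honor_exclusions)
            if sd_um == 0:
                children.append(offs)
                placed = c
                break
            children.append(offs[ok])
            placed += int(ok.sum())
    coords = np.vstack(children) if children else np.empty((0, 3))
    return PointPattern3D(coords, region=np.full(coords.shape[0], region.name,
                                                 dtype=object))


def generate_bundles(region: Region3D, target_fraction: float = BUNDLE_FRACTION,
                     tube_radius_um: float = 100.0, seed=None,
                     tolerance: float = 0.01, max_tubes: int = 10_000
                     ) -> List[TubeExclusion]:
    """Union of anterior–posterior tubes excluding ~``target_fraction`` of
    the region volume (measured by Monte Carlo, within ±``tolerance``)."""
    if not (0 <= target_fraction < 0.9):
        raise ValueError("target fraction must be in [0, 0.9)")
    if target_fraction == 0:
        return []
    rng = np.random.default_rng(seed)
    probes = region._mc_points_inside(120_000, rng)
    if probes.shape[0] == 0:
        raise GeometryError("region admits no probe points")
    lo, hi = region.bounding_box()
    excluded = np.zeros(probes.shape[0], dtype=bool)
    tubes: List[TubeExclusion] = []
    while excluded.mean() < target_fraction - tolerance / 2:
        if len(tubes) >= max_tubes:
            raise GeometryError(
                f"could not reach exclusion fraction {target_fraction} with "
                f"radius {tube_radius_um} µm"
            )
        center = (rng.uniform(lo[0], hi[0]), rng.uniform(lo[2], hi[2]))
        tube = TubeExclusion(center, tube_radius_um)
        hit = tube.contains(probes)
        gain = (hit & ~excluded).mean()
        if gain == 0:
            continue
        if excluded.mean() + gain > target_fraction + tolerance:
            continue  # would overshoot; try another placement
        tubes.append(tube)
        excluded |= hit
    return tubes


def _draw_diameters(rng: np.random.Generator, n: int, mean_um: float) -> np.ndarray:
    d = rng.normal(mean_um, DIAMETER_SD_UM, size=n)
    return np.clip(d, 10.0, None)


def generate_region_pattern(name: str, hemisphere: str, seed=None, rng=None,
                            with_bundles: bool = True) -> PointPattern3D:
    """One structure/hemisphere at its reported count, with the documented
    A–P gradient for CPu and NB, CSR otherwise, and bundle exclusions in CPu."""
    if rng is None:
        rng = np.random.default_rng(seed)
    row = REGION_TABLE[name]
    n = row[0] if hemisphere == "L" else row[1]
    region = make_region_fixture(name, hemisphere)
    if name == "CPu" and with_bundles:
        region.exclusion_zones = generate_bundles(
            region, BUNDLE_FRACTION, seed=rng.integers(2**31))
    if name in GRADIENT_RATIOS:
        pat = generate_gradient(region, n, ratio=GRADIENT_RATIOS[name], rng=rng)
    else:
        pat = generate_csr(region, n, rng=rng)
    pat.region = np.full(n, name, dtype=object)
    pat.hemisphere = np.full(n, hemisphere, dtype=object)
    pat.diameter_um = _draw_diameters(rng, n, row[4])
    return pat


def generate_bilateral_dataset(seed=None, with_bundles: bool = True) -> PointPattern3D:
    """All five structures, both hemispheres, at their reported counts."""
    rng = np.random.default_rng(seed)
    parts = [
        generate_region_pattern(name, hemi, rng=rng, with_bundles=with_bundles)
        for name in REGION_TABLE
        for hemi in ("L", "R")
    ]
    return concatenate_patterns(parts)
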