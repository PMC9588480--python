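"""Density summaries, hemispheric comparisons, and the quadrat-count F-test
for equality of point densities between two sub-windows (Illian et al.).

For counts n1, n2 observed in windows of volume v1, v2 under a homogeneous
Poisson model, the statistic

    F = v2 · (2·n1 + 1) / (v1 · (2·n2 + 1)),   df = (2·n1 + 1, 2·n2 + 1)

is approximately F-distributed under the null of equal intensity; F > 1
indicates window 1 is denser.  (The orientation is fixed by requiring the
reported df pairs and F values of the reference dataset to be mutually
consistent; the swapped orientation is also returned.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import pandas as pd
from scipy import stats

from .geometry import PointPattern3D, Region3D


def density(count: int, volume_mm3: float) -> float:
    """Point density in mm⁻³ (exact quotient)."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / volume_mm3


@dataclass
class DensitySummary:
    """Per-structure and per-hemisphere density bookkeeping."""

    table: pd.DataFrame              # index: region; columns: count_L/R, volume_L/R, density_L/R
    totals: Dict[str, Dict[str, float]]  # hemisphere -> {count, volume, density}
    count_difference: int            # |left - right|
    count_difference_pct: float      # of grand total
    density_difference: float        # |left - right| overall densities, mm^-3
    proportions: Dict[str, float]    # region -> share of grand total


def hemispheric_summary(counts: Dict[str, Tuple[int, int]],
                        volumes: Dict[str, Tuple[float, float]]) -> DensitySummary:
    """Summarize a per-region × hemisphere table of counts and volumes.

    ``counts[region] = (left, right)``; likewise volumes (mm³).  Reproduces
    per-cell densities, hemispheric totals and densities, the absolute
    left–right count difference and its percentage of the grand total, and
    each region's share of all cells.
    """
    missing = sorted(set(counts) ^ set(volumes))
    if missing:
        raise ValueError(f"count/volume cells missing for regions: {missing}")
    rows = {}
    for region in counts:
        (cl, cr), (vl, vr) = counts[region], volumes[region]
        rows[region] = dict(count_L=cl, count_R=cr, volume_L=vl, volume_R=vr,
                            density_L=density(cl, vl), density_R=density(cr, vr))
    table = pd.DataFrame.from_dict(rows, orient="index")
    totals = {}
    for hemi in ("L", "R"):
        c = int(table[f"count_{hemi}"].sum())
        v = float(table[f"volume_{hemi}"].sum())
        totals[hemi] = dict(count=c, volume=v, density=density(c, v))
    grand = totals["L"]["count"] + totals["R"]["count"]
    diff = abs(totals["L"]["count"] - totals["R"]["count"])
    return DensitySummary(
        table=table,
        totals=totals,
        count_difference=diff,
        count_difference_pct=100.0 * diff / grand,
        density_difference=abs(totals["L"]["density"] - totals["R"]["density"]),
        proportions={r: (rows[r]["count_L"] + rows[r]["count_R"]) / grand
                     for r in rows},
    )


@dataclass
class FTestResult:
    F: float
    df: Tuple[int, int]
    p_one_sided: float
    p_two_sided: float
    F_swapped: float
    df_swapped: Tuple[int, int]


def homogeneity_f_test(n1: int, v1: float, n2: int, v2: float) -> FTestResult:
    """Test equality of point density between two windows.

    F > 1 indicates window 1 denser; the one-sided p is P(F' ≥ F) under the
    null.  Both df orientations are reported.
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError("window volumes must be positive")
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    d1, d2 = 2 * n1 + 1, 2 * n2 + 1
    F = (v2 * d1) / (v1 * d2)
    p_one = float(stats.f.sf(F, d1, d2))
    p_two = float(2.0 * min(stats.f.sf(F, d1, d2), stats.f.cdf(F, d1, d2)))
    return FTestResult(F=float(F), df=(d1, d2), p_one_sided=p_one,
                       p_two_sided=min(p_two, 1.0),
                       F_swapped=float((v1 * d2) / (v2 * d1)),
                       df_swapped=(d2, d1))


def split_anterior_posterior(pattern: PointPattern3D, region: Region3D,
                             plane="median"):
    """Split a pattern at a Y plane into anterior/posterior sub-windows.

    ``plane`` is a Y threshold in µm or "median" (the plane bisecting the
    region volume).  Returns ((n_ant, v_ant), (n_post, v_post)) with volumes
    in mm³; anterior = smaller Y (more anterior in this frame).
    """
    if plane == "median":
        plane = region.y_median_plane()
    plane = float(plane)
    v_ant = region.clipped_volume_below_y(plane)
    v_post = region.volume_mm3 - v_ant
    if v_ant <= 0 or v_post <= 0:
        raise ValueError("degenerate split: one side has no volume")
    ant = pattern.coords[:, 1] <= plane
    n_ant, n_post = int(ant.sum()), int((~ant).sum())
    return (n_ant, v_ant), (n_post, v_post)


def anterior_posterior_f_test(pattern: PointPattern3D, region: Region3D,
                              plane="median") -> FTestResult:
    """Convenience: split at a Y plane and run the homogeneity F-test
    (window 1 = anterior)."""
    (n1, v1), (n2, v2) = split_anterior_posterior(pattern, region, plane)
    return homogeneity_f_test(n1, v1, n2, v2)
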