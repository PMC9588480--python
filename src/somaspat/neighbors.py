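"""Nearest-neighbor distances, the undirected nearest-neighbor graph, its
connected-component "clusters", and robustness of the cluster-size histogram
to coordinate noise.

The NN graph joins each point to its single nearest neighbor (ties broken by
lowest index) and symmetrizes; every node therefore has degree ≥ 1 and every
connected component has at least two members.  Component sizes are the
cluster sizes: regular arrangements give many mutual pairs (size 2–3),
clustered ones longer chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from ._seeds import as_seedseq
from .geometry import PointPattern3D, Region3D
from .synthetic import generate_csr


def knn_distances(pattern: PointPattern3D, k: int = 10) -> np.ndarray:
    """(n, k) exact Euclidean distances to the 1st..k-th neighbor (µm)."""
    if pattern.n <= k:
        raise ValueError(f"need more than k={k} points, got n={pattern.n}")
    tree = cKDTree(pattern.coords)
    d, _ = tree.query(pattern.coords, k=k + 1)
    return d[:, 1:]


def nearest_neighbor_indices(pattern: PointPattern3D) -> np.ndarray:
    """Index of each point's nearest neighbor; exact ties resolved by lowest
    index (deterministic for lattice fixtures)."""
    if pattern.n < 2:
        raise ValueError("need at least 2 points")
    tree = cKDTree(pattern.coords)
    d, idx = tree.query(pattern.coords, k=2)
    # with coincident points the tree may return i itself in either slot
    nn = np.where(idx[:, 1] == np.arange(pattern.n), idx[:, 0], idx[:, 1])
    nn_d = d[:, 1]
    # resolve exact ties (including duplicates) deterministically
    for i in range(pattern.n):
        cands = tree.query_ball_point(pattern.coords[i], nn_d[i] * (1 + 1e-12))
        cands = [c for c in cands if c != i and
                 np.linalg.norm(pattern.coords[c] - pattern.coords[i]) <= nn_d[i] * (1 + 1e-12)]
        if cands:
            nn[i] = min(cands)
    return nn


@dataclass
class ClusterGraph:
    """Symmetrized nearest-neighbor graph with connected components."""

    n: int
    edges: np.ndarray                  # (m, 2) deduplicated undirected edges
    labels: np.ndarray                 # component label per node
    components: List[np.ndarray]       # node index arrays
    size_histogram: Dict[int, int]     # component size -> frequency
    nn_index: np.ndarray               # NN(i) per node
    nn_distance: np.ndarray            # |i - NN(i)| per node (µm)


def nn_graph(pattern: PointPattern3D) -> ClusterGraph:
    """Build the undirected NN graph and its component-size histogram."""
    nn = nearest_neighbor_indices(pattern)
    n = pattern.n
    i = np.arange(n)
    und = np.sort(np.column_stack([i, nn]), axis=1)
    edges = np.unique(und, axis=0)
    adj = sparse.coo_matrix(
        (np.ones(edges.shape[0]), (edges[:, 0], edges[:, 1])), shape=(n, n))
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    components = [np.flatnonzero(labels == c) for c in range(n_comp)]
    sizes = [len(c) for c in components]
    hist: Dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    nn_d = np.linalg.norm(pattern.coords - pattern.coords[nn], axis=1)
    return ClusterGraph(n=n, edges=edges, labels=labels, components=components,
                        size_histogram=hist, nn_index=nn, nn_distance=nn_d)


@dataclass
class NNComparisonResult:
    """Observed vs CSR-simulated mean k-NN distances."""

    k_values: np.ndarray
    observed_mean: np.ndarray     # mean distance per k (µm)
    observed_sd: np.ndarray
    observed_se: np.ndarray
    sim_mean: np.ndarray          # mean over simulations of per-sim means
    sim_lo: np.ndarray            # 2.5th percentile of per-sim means
    sim_hi: np.ndarray            # 97.5th percentile


def nn_compare_to_csr(pattern: PointPattern3D, region: Region3D,
                      n_sims: int = 1000, k: int = 10, seed=None,
                      honor_exclusions: bool = False) -> NNComparisonResult:
    """Mean k-NN distance per k against its CSR distribution (same region,
    same n).  Observed below the band ⇒ clustering; above ⇒ regularity."""
    obs = knn_distances(pattern, k)
    child_seeds = as_seedseq(seed).spawn(n_sims)
    sim_means = np.empty((n_sims, k))
    for s in range(n_sims):
        rng = np.random.default_rng(child_seeds[s])
        sim = generate_csr(region, pattern.n, rng=rng,
                           honor_exclusions=honor_exclusions)
        sim_means[s] = knn_distances(sim, k).mean(axis=0)
    return NNComparisonResult(
        k_values=np.arange(1, k + 1),
        observed_mean=obs.mean(axis=0),
        observed_sd=obs.std(axis=0, ddof=1),
        observed_se=obs.std(axis=0, ddof=1) / np.sqrt(pattern.n),
        sim_mean=sim_means.mean(axis=0),
        sim_lo=np.percentile(sim_means, 2.5, axis=0),
        sim_hi=np.percentile(sim_means, 97.5, axis=0),
    )


def poisson_mean_nn_distance(intensity_per_mm3: float) -> float:
    """Closed-form mean 1-NN distance (µm) of a homogeneous Poisson process:
    Γ(4/3) · (4πλ/3)^(-1/3)."""
    from scipy.special import gamma
    lam_um3 = intensity_per_mm3 / 1e9
    return float(gamma(4.0 / 3.0) * (4.0 * np.pi * lam_um3 / 3.0) ** (-1.0 / 3.0))


def histogram_tv_distance(h1: Dict[int, int], h2: Dict[int, int]) -> float:
    """Total-variation distance between two cluster-size histograms,
    normalized as distributions over sizes."""
    sizes = set(h1) | set(h2)
    t1 = sum(h1.values())
    t2 = sum(h2.values())
    return 0.5 * sum(abs(h1.get(s, 0) / t1 - h2.get(s, 0) / t2) for s in sizes)


def noise_robustness(pattern: PointPattern3D, sd_um: float, n_reps: int = 10,
                     seed=None) -> np.ndarray:
    """TV distance between the original and noise-perturbed cluster-size
    histograms, per repetition of isotropic Gaussian coordinate noise."""
    if sd_um < 0:
        raise ValueError("noise sd must be non-negative")
    base = nn_graph(pattern).size_histogram
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        noisy = PointPattern3D(
            pattern.coords + rng.normal(0.0, sd_um, size=pattern.coords.shape)
            if sd_um > 0 else pattern.coords.copy())
        out[r] = histogram_tv_distance(base, nn_graph(noisy).size_histogram)
    return out
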