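"""k-NN distances, the symmetrized nearest-neighbor graph, cluster-size
histograms, CSR comparison bands, and noise robustness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaspat.geometry import BoxRegion, PointPattern3D
from somaspat.neighbors import (
    histogram_tv_distance,
    knn_distances,
    nn_graph,
    noise_robustness,
    poisson_mean_nn_distance,
)
from somaspat.synthetic import generate_csr


def lattice_pattern(m=3, spacing=50.0):
    g = np.arange(m) * spacing
    gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
    return PointPattern3D(np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))


class TestKnnDistances:
    def test_pair(self):
        pat = PointPattern3D([[0, 0, 0], [100.0, 0, 0]])
        d = knn_distances(pat, 1)
        np.testing.assert_allclose(d, [[100.0], [100.0]])

    def test_grid_first_neighbor(self):
        d = knn_distances(lattice_pattern(3, 50.0), 1)
        np.testing.assert_allclose(d, 50.0)

    def test_matches_brute_force_sort(self, rng):
        coords = rng.uniform(0, 1000, (200, 3))
        got = knn_distances(PointPattern3D(coords), 10)
        diffs = coords[:, None, :] - coords[None, :, :]
        d = np.linalg.norm(diffs, axis=2)
        np.fill_diagonal(d, np.inf)
        want = np.sort(d, axis=1)[:, :10]
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_needs_enough_points(self):
        with pytest.raises(ValueError):
            knn_distances(PointPattern3D(np.zeros((3, 3))), 5)


class TestNNGraph:
    def test_three_collinear_points_single_component(self):
        pat = PointPattern3D([[0, 0, 0], [1000.0, 0, 0], [3000.0, 0, 0]])
        g = nn_graph(pat)
        assert len(g.components) == 1
        assert g.size_histogram == {3: 1}
        edges = {tuple(e) for e in g.edges}
        assert edges == {(0, 1), (1, 2)}

    def test_two_far_pairs(self):
        pat = PointPattern3D([[0, 0, 0], [10.0, 0, 0],
                              [5000, 5000, 5000], [5000, 5000, 5010.0]])
        g = nn_graph(pat)
        assert g.size_histogram == {2: 2}

    def test_matches_brute_force_components(self, rng):
        coords = rng.uniform(0, 1000, (500, 3))
        g = nn_graph(PointPattern3D(coords))
        # oracle: explicit NN via full distance matrix, then union-find
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = d.argmin(axis=1)
        parent = list(range(500))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in enumerate(nn):
            parent[find(i)] = find(int(j))
        labels = np.array([find(i) for i in range(500)])
        want = {tuple(sorted(np.flatnonzero(labels == l)))
                for l in set(labels)}
        got = {tuple(sorted(c)) for c in g.components}
        assert got == want
        assert np.array_equal(g.nn_index, nn)

    def test_degree_and_component_invariants(self, rng):
        coords = rng.uniform(0, 2000, (300, 3))
        g = nn_graph(PointPattern3D(coords))
        assert min(len(c) for c in g.components) >= 2
        assert sum(s * f for s, f in g.size_histogram.items()) == 300
        # NN-edge length equals 1-NN distance
        d1 = knn_distances(PointPattern3D(coords), 1).ravel()
        np.testing.assert_allclose(g.nn_distance, d1, rtol=1e-12)

    def test_lattice_ties_resolved_deterministically(self):
        g1 = nn_graph(lattice_pattern(3, 50.0))
        g2 = nn_graph(lattice_pattern(3, 50.0))
        assert np.array_equal(g1.nn_index, g2.nn_index)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(*[st.floats(0, 500, allow_nan=False)] * 3),
                    min_size=2, max_size=40))
    def test_partition_invariants_for_arbitrary_patterns(self, points):
        """For any finite configuration (ties and duplicates included):
        components partition the nodes, every component has ≥ 2 members,
        and no node is its own nearest neighbor."""
        g = nn_graph(PointPattern3D(np.asarray(points, dtype=float)))
        n = len(points)
        assert sum(s * f for s, f in g.size_histogram.items()) == n
        assert min(len(c) for c in g.components) >= 2
        assert np.all(g.nn_index != np.arange(n))


def test_csr_mean_nn_matches_poisson_closed_form():
    """Interior-point mean 1-NN distance versus Γ(4/3)(4πλ/3)^(-1/3)."""
    region = BoxRegion((0, 0, 0), (2000, 2000, 2000))
    n = 6000
    lam = n / region.volume_mm3
    expected = poisson_mean_nn_distance(lam)
    means = []
    for s in range(5):
        pat = generate_csr(region, n, seed=s)
        d1 = knn_distances(pat, 1).ravel()
        margin = 2 * expected
        interior = region.boundary_clearance(pat.coords) > margin
        means.append(d1[interior].mean())
    assert np.mean(means) == pytest.approx(expected, rel=0.05)


class TestNoiseRobustness:
    def test_zero_noise_identical_histogram(self, csr_cube_pattern):
        out = noise_robustness(csr_cube_pattern, 0.0, n_reps=3, seed=0)
        np.testing.assert_allclose(out, 0.0)

    def test_small_noise_small_change(self, unit_cube):
        # NN spacing ~80 µm at this density; 1 µm noise barely moves it
        pat = generate_csr(unit_cube, 1200, seed=6)
        out = noise_robustness(pat, 1.0, n_reps=5, seed=1)
        assert np.all(out < 0.05)

    def test_huge_noise_converges_to_csr_histogram(self, unit_cube):
        """Noise ≫ spacing destroys structure: the perturbed histogram looks
        like a fresh CSR histogram, not like the original clustered one."""
        rng = np.random.default_rng(12)
        # tight clusters: characteristic spacing ~5 µm
        centers = rng.uniform(100, 900, (40, 3))
        coords = np.repeat(centers, 5, axis=0) + rng.normal(0, 5, (200, 3))
        clustered = PointPattern3D(coords)
        base = nn_graph(clustered).size_histogram
        noisy = PointPattern3D(coords + rng.normal(0, 400, coords.shape))
        csr_hist = nn_graph(generate_csr(unit_cube, 200, seed=3)).size_histogram
        d_csr = histogram_tv_distance(nn_graph(noisy).size_histogram, csr_hist)
        d_base = histogram_tv_distance(nn_graph(noisy).size_histogram, base)
        assert d_csr < d_base


def test_tv_distance_properties():
    assert histogram_tv_distance({2: 5}, {2: 50}) == 0.0
    assert histogram_tv_distance({2: 5}, {3: 5}) == 1.0
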