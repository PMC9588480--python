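"""Kernel intensity, K_inhom, conditional inhomogeneous-Poisson simulation,
and the Monte Carlo rank test."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from somaspat.geometry import BoxRegion, PointPattern3D
from somaspat.inhomogeneous import (
    IntensityField,
    k_inhom,
    kernel_intensity,
    monte_carlo_rank_test,
    silverman_bandwidth,
    simulate_inhom_poisson,
)
from somaspat.ripley import k_function
from somaspat.synthetic import generate_csr, generate_gradient


class ConstantField:
    """Stand-in intensity with a fixed value (mm⁻³)."""

    def __init__(self, value):
        self.value = value

    def __call__(self, points):
        points = np.atleast_2d(points)
        return np.full(points.shape[0], self.value)


class TestKernelIntensity:
    def test_csr_center_value(self, unit_cube):
        pat = generate_csr(unit_cube, 5000, seed=2)
        field = kernel_intensity(pat, unit_cube)
        assert field([500.0, 500, 500]) == pytest.approx(5000.0, rel=0.10)

    def test_integral_close_to_n(self, unit_cube):
        pat = generate_csr(unit_cube, 800, seed=3)
        field = kernel_intensity(pat, unit_cube)
        rng = np.random.default_rng(99)
        probes = rng.uniform(0, 1000, (20_000, 3))
        integral = field(probes).mean() * unit_cube.volume_mm3
        assert integral == pytest.approx(800, rel=0.05)

    def test_kde_scaling_identity(self, unit_cube):
        """Doubling coordinates and bandwidth scales λ by 1/8."""
        rng = np.random.default_rng(5)
        coords = rng.uniform(200, 800, (60, 3))
        big = BoxRegion((0, 0, 0), (2000, 2000, 2000))
        f1 = IntensityField(coords, 50.0, unit_cube, edge_corrected=False)
        f2 = IntensityField(2 * coords, 100.0, big, edge_corrected=False)
        x = np.array([400.0, 500, 600])
        assert f2(2 * x) == pytest.approx(f1(x) / 8.0, rel=1e-9)

    def test_two_blob_pattern_peaks_at_blobs(self, unit_cube):
        rng = np.random.default_rng(8)
        blob1 = rng.normal(0, 30, (80, 3)) + [250, 500, 500]
        blob2 = rng.normal(0, 30, (80, 3)) + [750, 500, 500]
        pat = PointPattern3D(np.vstack([blob1, blob2]))
        field = kernel_intensity(pat, unit_cube, bandwidth=60.0)
        assert field([250.0, 500, 500]) > field([500.0, 500, 500])

    def test_coincident_points_rejected(self, unit_cube):
        pat = PointPattern3D(np.zeros((10, 3)) + 500.0)
        with pytest.raises(ValueError):
            kernel_intensity(pat, unit_cube)

    def test_silverman_matches_rule(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(0, 100, (200, 3))
        h = silverman_bandwidth(coords)
        sig = np.exp(np.log(coords.std(axis=0, ddof=1)).mean())
        expected = (4 / 5) ** (1 / 7) * 200 ** (-1 / 7) * sig
        assert h == pytest.approx(expected)


class TestKInhom:
    def test_constant_intensity_identity(self, csr_cube_pattern):
        """With λ = n/|V|, K_inhom(r) = |V|·K(r) at every radius."""
        n = csr_cube_pattern.n
        vol = 1.0
        radii = np.linspace(30, 1400, 30)
        field = ConstantField(n / vol)
        ki = k_inhom(csr_cube_pattern, field, radii)
        k = k_function(csr_cube_pattern, vol, radii).k_observed
        np.testing.assert_allclose(ki, vol * k, rtol=1e-9)

    def test_single_pair_arithmetic(self):
        pat = PointPattern3D([[0, 0, 0], [100.0, 0, 0]])
        ki = k_inhom(pat, ConstantField(2.0), np.array([50.0, 150.0]))
        np.testing.assert_allclose(ki, [0.0, 0.5])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial, unit_cube):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(10, 200))
        pat = generate_gradient(unit_cube, n, ratio=2.0,
                                rng=np.random.default_rng(trial))
        field = kernel_intensity(pat, unit_cube)
        lam = field(pat.coords)
        radii = np.sort(rng.uniform(50, 1200, 8))
        got = k_inhom(pat, field, radii)
        d = squareform(pdist(pat.coords))
        np.fill_diagonal(d, np.inf)
        w = 1.0 / np.outer(lam, lam)
        want = np.array([(w * (d <= r)).sum() for r in radii])
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_zero_intensity_at_point_rejected(self, csr_cube_pattern):
        with pytest.raises(ValueError):
            k_inhom(csr_cube_pattern, ConstantField(0.0), np.array([100.0]))


class TestInhomPoissonSimulation:
    def test_seed_determinism(self, unit_cube):
        pat = generate_csr(unit_cube, 100, seed=4)
        field = kernel_intensity(pat, unit_cube)
        a = simulate_inhom_poisson(field, unit_cube, 50, seed=9)
        b = simulate_inhom_poisson(field, unit_cube, 50, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_linear_gradient_halves_ratio(self, unit_cube):
        """λ with endpoint ratio 2 → anterior:posterior half-count
        expectation 5:3 in a box."""

        class LinearField:
            def __call__(self, pts):
                pts = np.atleast_2d(pts)
                return 2.0 - pts[:, 1] / 1000.0

            def max_over_region(self):
                return 2.0

        n = 4000
        sim = simulate_inhom_poisson(LinearField(), unit_cube, n, seed=10)
        frac = (sim.coords[:, 1] <= 500.0).mean()
        expected = 1.75 / (1.75 + 1.25)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 5 * se


class TestRankTest:
    def test_minimum_p_with_99_nulls(self):
        rng = np.random.default_rng(0)
        nulls = rng.normal(0, 1, (99, 10))
        observed = np.full(10, 50.0)  # more extreme than every null
        rank, p = monte_carlo_rank_test(observed, nulls)
        assert p == pytest.approx(0.01)
        assert rank == 100

    def test_rank_arithmetic_with_distinct_criteria(self):
        nulls = np.arange(9.0)[:, None] * np.ones((9, 4))
        observed = nulls[4].copy()  # ties one null exactly
        _, p = monte_carlo_rank_test(observed, nulls)
        ref = nulls.mean(axis=0)
        crit_obs = np.abs(observed - ref).sum()
        n_ge = (np.abs(nulls - ref).sum(axis=1) >= crit_obs).sum()
        assert p == pytest.approx((1 + n_ge) / 10)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_rank_test(np.zeros(5), np.zeros((10, 4)))
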