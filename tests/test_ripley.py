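"""Uncorrected 3D Ripley K: formula cases, brute-force oracle equivalence,
monotonicity, CSR behaviour, envelopes, and the paired-t comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from somaspat.geometry import PointPattern3D
from somaspat.ripley import csr_envelope, default_radii, k_function, paired_t_compare
from somaspat.synthetic import generate_csr


def brute_force_k(coords, volume_mm3, radii):
    """O(n²) double-loop oracle."""
    n = coords.shape[0]
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    return np.array([volume_mm3 * (d <= r).sum() / n**2 for r in radii])


class TestKFunction:
    def test_single_point_is_zero(self):
        pat = PointPattern3D([[10.0, 10, 10]])
        res = k_function(pat, 1.0, np.array([50.0, 100.0]))
        assert np.all(res.k_observed == 0)

    def test_two_point_step(self):
        pat = PointPattern3D([[0, 0, 0], [100.0, 0, 0]])
        res = k_function(pat, 1.0, np.array([50.0, 100.0, 200.0]))
        np.testing.assert_allclose(res.k_observed, [0.0, 0.5, 0.5])

    def test_tie_counts_as_within(self):
        """D = r exactly counts as ≤ r, per the indicator convention."""
        pat = PointPattern3D([[0, 0, 0], [100.0, 0, 0]])
        res = k_function(pat, 1.0, np.array([100.0]))
        assert res.k_observed[0] == 0.5

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 200))
        coords = rng.uniform(0, 1000, (n, 3))
        radii = np.sort(rng.uniform(20, 1500, 12))
        got = k_function(PointPattern3D(coords), 1.0, radii).k_observed
        want = brute_force_k(coords, 1.0, radii)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_monotone_and_saturates(self, csr_cube_pattern):
        radii = np.linspace(10, 2000, 40)
        res = k_function(csr_cube_pattern, 1.0, radii)
        assert np.all(np.diff(res.k_observed) >= 0)
        n = csr_cube_pattern.n
        assert res.k_observed[-1] == pytest.approx(1.0 * (n - 1) / n)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            k_function(PointPattern3D(np.empty((0, 3))), 1.0, np.array([1.0]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(*[st.floats(0, 1000, allow_nan=False)] * 3),
                    min_size=2, max_size=40))
    def test_k_properties_hold_for_arbitrary_patterns(self, points):
        """K is zero below the minimum pair distance, non-decreasing, and
        saturates at |V|(n-1)/n beyond the pattern diameter — for any
        finite point configuration."""
        coords = np.asarray(points, dtype=float)
        n = coords.shape[0]
        d = pdist(coords)
        radii = np.linspace(1.0, 2000.0, 12)
        k = k_function(PointPattern3D(coords), 1.0, radii).k_observed
        assert np.all(np.diff(k) >= 0)
        assert np.all(k[radii < (d.min() if d.size else np.inf)] == 0)
        assert k[-1] == pytest.approx((n - 1) / n)


class TestCSREnvelope:
    def test_contains_requested_number_of_simulations(self, unit_cube,
                                                      csr_cube_pattern):
        radii = np.linspace(50, 400, 5)
        env = csr_envelope(csr_cube_pattern, unit_cube, n_sims=2, radii=radii,
                           seed=0)
        assert env.simulations.shape == (2, 5)

    def test_csr_mean_matches_sphere_volume_at_small_r(self, unit_cube):
        """E[K(r)] ≈ (4/3)πr³ for r ≪ region size (the uncorrected edge
        bias is ≈ (9/8)·r/L for a cube, so r/L ≤ 0.03 stays within 5%);
        at larger r the bias is negative."""
        radii = np.array([20.0, 30.0, 400.0, 800.0])
        pat = generate_csr(unit_cube, 2000, seed=21)
        env = csr_envelope(pat, unit_cube, n_sims=100, radii=radii, seed=22)
        sphere = 4.0 / 3.0 * np.pi * (radii / 1000.0) ** 3
        mean = env.sim_mean
        assert mean[0] == pytest.approx(sphere[0], rel=0.05)
        assert mean[1] == pytest.approx(sphere[1], rel=0.05)
        # direction of the edge bias at large r
        assert mean[2] <= sphere[2]
        assert mean[3] <= sphere[3]

    def test_default_radii_give_df_99(self, unit_cube):
        radii = default_radii(unit_cube)
        assert radii.shape[0] == 100
        d = np.diff(radii)
        np.testing.assert_allclose(d, d[0])


class TestPairedT:
    def test_identical_curves(self):
        t, df, p = paired_t_compare(np.arange(5.0), np.arange(5.0))
        assert (t, p) == (0.0, 1.0)
        assert df == 4

    def test_textbook_arithmetic(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = paired_t_compare(obs, np.zeros(4))
        assert t == pytest.approx(3.873, abs=1e-3)
        assert df == 3

    def test_hundred_point_grid_reports_df_99(self, unit_cube):
        radii = default_radii(unit_cube)
        rng = np.random.default_rng(0)
        t, df, _ = paired_t_compare(rng.uniform(size=100),
                                    rng.uniform(size=100))
        assert df == 99

    def test_degenerate_zero_variance(self):
        t, df, p = paired_t_compare(np.ones(4), np.zeros(4))
        assert np.isinf(t) and p == 0.0
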