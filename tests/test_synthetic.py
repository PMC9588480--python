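"""Synthetic fixture generators: reported counts/volumes, gradients,
clustering, bundles, determinism."""

import numpy as np
import pytest

from somaspat.geometry import BoxRegion
from somaspat.synthetic import (
    REGION_TABLE,
    generate_bilateral_dataset,
    generate_bundles,
    generate_csr,
    generate_gradient,
    generate_thomas,
    gradient_anterior_fraction,
    make_region_fixture,
)


class TestRegionFixtures:
    @pytest.mark.parametrize("name,hemi,expected", [
        ("GP", "L", 2.74), ("CPu", "R", 15.95), ("S", "L", 0.89),
        ("NB", "R", 2.95), ("NA", "L", 2.13),
    ])
    def test_fixture_volume_matches_report(self, name, hemi, expected):
        region = make_region_fixture(name, hemi)
        assert region.volume_mm3 == pytest.approx(expected, rel=0.005)

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            make_region_fixture("XX", "L")


class TestCSR:
    def test_density_from_counts_and_volume(self):
        # bilateral GP: 508 cells in 4.81 mm³ ≈ 105.6 mm⁻³
        parts = [make_region_fixture("GP", h) for h in ("L", "R")]
        total_vol = sum(r.volume_mm3 for r in parts)
        assert 508 / total_vol == pytest.approx(105.6, abs=0.1)
        pats = [generate_csr(r, n, seed=i)
                for i, (r, n) in enumerate(zip(parts, (308, 200)))]
        assert sum(p.n for p in pats) == 508

    def test_seed_contract(self):
        region = make_region_fixture("GP", "L")
        a = generate_csr(region, 40, seed=1)
        b = generate_csr(region, 40, seed=1)
        c = generate_csr(region, 40, seed=2)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)

    def test_empty(self):
        assert generate_csr(make_region_fixture("S", "L"), 0, seed=0).n == 0


class TestGradient:
    def test_all_points_inside(self):
        region = make_region_fixture("NB", "L")
        pat = generate_gradient(region, 300, ratio=2.0, seed=4)
        assert region.contains(pat.coords).all()
        assert pat.n == 300

    def test_anterior_fraction_matches_closed_form(self):
        """Split at the volume-median plane: anterior share of a linear
        endpoint-ratio-2.1 gradient in an ellipsoid follows the analytic
        cross-section integral."""
        region = make_region_fixture("CPu", "L")
        n = 4000
        pat = generate_gradient(region, n, ratio=2.1, seed=11)
        plane = region.y_median_plane()
        frac = (pat.coords[:, 1] <= plane).mean()
        expected = gradient_anterior_fraction(2.1)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 5 * se

    def test_ratio_one_is_csr_like(self):
        """ratio=1 gradient and CSR agree in distribution (two-sample test
        on NN-distance means, non-significant in most paired runs)."""
        from scipy.stats import ttest_ind

        from somaspat.neighbors import knn_distances
        region = BoxRegion((0, 0, 0), (1000, 1000, 1000))
        fails = 0
        runs = 20
        ss = np.random.SeedSequence(88).spawn(runs)
        for i in range(runs):
            s1, s2 = ss[i].spawn(2)
            a = generate_gradient(region, 150, ratio=1.0,
                                  rng=np.random.default_rng(s1))
            b = generate_csr(region, 150, rng=np.random.default_rng(s2))
            _, p = ttest_ind(knn_distances(a, 1).ravel(),
                             knn_distances(b, 1).ravel())
            fails += p < 0.01
        assert fails <= 3


class TestThomas:
    def test_zero_sd_children_coincide_with_parents(self):
        region = make_region_fixture("NA", "L")
        pat = generate_thomas(region, 20, 5.0, 0.0, seed=6)
        parents = generate_csr(region, 20, seed=None,
                               rng=np.random.default_rng(6))
        # every child sits exactly on some parent location
        from somaspat.neighbors import knn_distances
        if pat.n > 1:
            d1 = knn_distances(pat, 1)
            assert np.median(d1) == pytest.approx(0.0, abs=1e-9)

    def test_expected_total_count(self):
        region = make_region_fixture("CPu", "L")
        parents, mean = 50, 10.0
        counts = [generate_thomas(region, parents, mean, 50.0, seed=s).n
                  for s in range(8)]
        expect = parents * mean
        sd = np.sqrt(expect)
        assert abs(np.mean(counts) - expect) < 3 * sd / np.sqrt(len(counts))


class TestBundles:
    def test_zero_fraction_empty(self):
        assert generate_bundles(make_region_fixture("CPu", "L"), 0.0) == []

    def test_target_fraction_reached(self):
        region = make_region_fixture("CPu", "L")
        region.exclusion_zones = generate_bundles(region, 0.268, seed=5)
        assert region.exclusion_fraction(seed=123) == pytest.approx(0.268,
                                                                    abs=0.01)

    def test_sampling_avoids_tubes(self):
        region = make_region_fixture("CPu", "L")
        tubes = generate_bundles(region, 0.268, seed=5)
        region.exclusion_zones = tubes
        pat = generate_csr(region, 400, seed=9, honor_exclusions=True)
        hit = np.zeros(pat.n, dtype=bool)
        for t in tubes:
            hit |= t.contains(pat.coords)
        assert not hit.any()


@pytest.fixture(scope="module")
def dataset():
    return generate_bilateral_dataset(seed=17, with_bundles=False)


class TestBilateralDataset:

    def test_total_count(self, dataset):
        assert dataset.n == 13_989

    def test_hemispheric_difference(self, dataset):
        left = (dataset.hemisphere == "L").sum()
        right = (dataset.hemisphere == "R").sum()
        assert abs(int(left) - int(right)) == 557

    def test_per_structure_counts(self, dataset):
        for name, row in REGION_TABLE.items():
            for hemi, expected in zip(("L", "R"), row[:2]):
                mask = (dataset.region == name) & (dataset.hemisphere == hemi)
                assert int(mask.sum()) == expected

    def test_every_point_labeled_and_inside_its_fixture(self, dataset):
        assert not any(r is None for r in dataset.region)
        for name in ("GP", "S"):
            for hemi in ("L", "R"):
                region = make_region_fixture(name, hemi)
                mask = (dataset.region == name) & (dataset.hemisphere == hemi)
                assert region.contains(dataset.coords[mask]).all()

    def test_byte_identical_under_same_seed(self):
        a = generate_bilateral_dataset(seed=3, with_bundles=False)
        b = generate_bilateral_dataset(seed=3, with_bundles=False)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.diameter_um, b.diameter_um)
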