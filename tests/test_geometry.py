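"""Region construction, volumes, membership, and constrained sampling."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.stats import chisquare

from somaspat.geometry import (
    BallRegion,
    BoxRegion,
    EllipsoidRegion,
    GeometryError,
    PointPattern3D,
    TubeExclusion,
    VoxelRegion,
    build_region,
    extract_ball_subregion,
    region_volume,
    sample_uniform,
)


class TestBuildRegion:
    def test_convex_hull_of_cube_corners(self, cube_corners):
        region = build_region(cube_corners, np.inf)
        assert region.volume_mm3 == pytest.approx(1.0)

    def test_unit_right_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1000, 0, 0], [0, 1000, 0], [0, 0, 1000.0]])
        region = build_region(pts, np.inf)
        assert region.volume_mm3 == pytest.approx(1.0 / 6.0)

    def test_alpha_complex_splits_distant_blobs(self, rng):
        """Finite alpha must not bridge two blobs 5 mm apart."""
        blob1 = rng.normal(0, 200, (20, 3))
        blob2 = rng.normal(0, 200, (20, 3)) + [5000, 0, 0]
        pts = np.vstack([blob1, blob2])
        alpha_region = build_region(pts, alpha_um=1000.0)
        hull_volume = ConvexHull(pts).volume / 1e9  # independent hull routine
        assert alpha_region.volume_mm3 < hull_volume
        # hull monotonicity
        assert build_region(pts, np.inf).volume_mm3 >= alpha_region.volume_mm3

    def test_degenerate_input_raises(self):
        coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0],
                             [0.5, 0.5, 0]])
        with pytest.raises(GeometryError):
            build_region(coplanar, np.inf)

    def test_too_small_alpha_raises(self, cube_corners):
        with pytest.raises(GeometryError):
            build_region(cube_corners, alpha_um=1.0)


class TestVolumesAndMembership:
    def test_voxel_region_volume(self):
        region = VoxelRegion(np.ones((10, 10, 10), dtype=bool), 100.0)
        assert region.volume_mm3 == pytest.approx(1.0)

    def test_zero_volume_rejected(self):
        region = VoxelRegion(np.zeros((4, 4, 4), dtype=bool), 100.0)
        with pytest.raises(GeometryError):
            region_volume(region)

    def test_cube_membership(self, unit_cube):
        assert unit_cube.contains(np.array([500.0, 500, 500]))
        assert not unit_cube.contains(np.array([2000.0, 0, 0]))
        # boundary counts as inside
        assert unit_cube.contains(np.array([0.0, 0, 0]))

    def test_nonfinite_point_rejected(self, unit_cube):
        with pytest.raises(GeometryError):
            unit_cube.contains(np.array([np.nan, 0, 0]))

    def test_tube_exclusion_blocks_axis(self, unit_cube):
        unit_cube.exclusion_zones = [TubeExclusion((500, 500), 100.0)]
        on_axis = np.array([500.0, 250, 500])
        assert unit_cube.contains(on_axis, honor_exclusions=False)
        assert not unit_cube.contains(on_axis, honor_exclusions=True)

    def test_sphere_voxel_vs_mesh_volume_agreement(self):
        """Voxelized and analytic spheres agree on volume within 2%."""
        r = 1000.0
        vs = 50.0
        n = int(2 * r / vs) + 2
        ax = (np.arange(n) + 0.5) * vs - r - vs
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = gx**2 + gy**2 + gz**2 <= r**2
        voxel = VoxelRegion(mask, vs, origin_um=(-r - vs, -r - vs, -r - vs))
        ball = BallRegion((0, 0, 0), r)
        assert voxel.volume_mm3 == pytest.approx(ball.volume_mm3, rel=0.02)


class TestSampleUniform:
    def test_empty_pattern(self, unit_cube):
        assert sample_uniform(unit_cube, 0, seed=1).n == 0

    def test_uniform_moments(self, unit_cube):
        pat = sample_uniform(unit_cube, 10_000, seed=7)
        se = 1000.0 / np.sqrt(12 * 10_000)
        for ax in range(3):
            assert abs(pat.coords[:, ax].mean() - 500.0) < 5 * se

    def test_exclusions_respected_and_octants_uniform(self, unit_cube):
        tube = TubeExclusion((500, 500), 282.0)  # ~25% of the cube volume
        unit_cube.exclusion_zones = [tube]
        pat = sample_uniform(unit_cube, 10_000, honor_exclusions=True, seed=3)
        assert not tube.contains(pat.coords).any()
        assert unit_cube.contains(pat.coords, honor_exclusions=True).all()
        # admissible-region octant counts consistent with uniformity
        octant = (
            (pat.coords[:, 0] > 500).astype(int)
            + 2 * (pat.coords[:, 1] > 500).astype(int)
            + 4 * (pat.coords[:, 2] > 500).astype(int)
        )
        counts = np.bincount(octant, minlength=8)
        _, p = chisquare(counts)
        assert p > 0.01

    def test_determinism(self, unit_cube):
        a = sample_uniform(unit_cube, 50, seed=5)
        b = sample_uniform(unit_cube, 50, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_tiny_admissible_fraction_raises(self, unit_cube):
        unit_cube.exclusion_zones = [TubeExclusion((500, 500), 1e6)]
        with pytest.raises(GeometryError):
            sample_uniform(unit_cube, 10, honor_exclusions=True, seed=1)


class TestBallSubregion:
    def test_centered_ball_volume(self):
        region = BoxRegion((0, 0, 0), (4000, 4000, 4000))
        pat = sample_uniform(region, 200, seed=9)
        sub, ball = extract_ball_subregion(pat, region, 1000.0,
                                           center=(2000, 2000, 2000))
        assert ball.volume_mm3 == pytest.approx(4.0 / 3.0 * np.pi)
        inside = np.linalg.norm(pat.coords - 2000.0, axis=1) <= 1000.0
        assert sub.n == inside.sum()

    def test_empty_subpattern_is_valid(self):
        region = BoxRegion((0, 0, 0), (4000, 4000, 4000))
        corner = PointPattern3D(np.full((10, 3), 100.0))
        sub, ball = extract_ball_subregion(corner, region, 1000.0,
                                           center=(2000, 2000, 2000))
        assert sub.n == 0
        assert ball.volume_mm3 > 0

    def test_csr_count_fraction_tracks_volume_fraction(self):
        region = BoxRegion((0, 0, 0), (2000, 2000, 2000))
        n = 4000
        pat = sample_uniform(region, n, seed=13)
        sub, ball = extract_ball_subregion(pat, region, 992.0, center="auto")
        frac = ball.volume_mm3 / region.volume_mm3
        se = np.sqrt(frac * (1 - frac) * n)
        assert abs(sub.n - n * frac) < 5 * se

    def test_no_placement_raises(self):
        region = BoxRegion((0, 0, 0), (1000, 1000, 1000))
        pat = sample_uniform(region, 10, seed=2)
        with pytest.raises(GeometryError):
            extract_ball_subregion(pat, region, 900.0, center="auto")


def test_ellipsoid_analytic_split_volume():
    ell = EllipsoidRegion((0, 0, 0), (1000, 2000, 1000))
    half = ell.clipped_volume_below_y(0.0)
    assert half == pytest.approx(ell.volume_mm3 / 2)
    assert ell.clipped_volume_below_y(2000.0) == pytest.approx(ell.volume_mm3)
    # y-median plane of a symmetric ellipsoid is its center plane
    assert abs(ell.y_median_plane()) < 1.0
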