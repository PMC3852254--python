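"""Unit and property tests for distances, quantiles, bands and polygons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from distfreecr import (
    ConvexRegion,
    DirectionGrid,
    PointSet,
    SimDesign,
    adjacent_crossover,
    contains,
    directional_band,
    empirical_quantile,
    region_from_bands,
    sample_bvn,
    signed_distances,
)
from distfreecr.geometry import DegenerateDataWarning, GeometryError


def _points(arr) -> PointSet:
    return PointSet(np.asarray(arr, dtype=float))


def _bands(pts, K, alpha):
    grid = DirectionGrid.equally_spaced(K)
    return [directional_band(pts, th, alpha) for th in grid.angles]


class TestSignedDistances:
    @pytest.mark.parametrize(
        "xy, theta, expected",
        [
            ((2.0, 3.0), 0.0, 3.0),  # distance to the horizontal axis is y
            ((1.0, 1.0), np.pi / 4, 0.0),  # point on the reference line
            ((0.0, 2.0), np.pi / 4, np.sqrt(2.0)),  # |y - x| / sqrt(2)
        ],
    )
    def test_known_distances(self, xy, theta, expected):
        d = signed_distances(_points([xy, (0, 0), (1, 0)]), theta)
        assert d[0] == pytest.approx(expected, abs=1e-12)

    def test_rejects_theta_out_of_range(self):
        with pytest.raises(GeometryError):
            signed_distances(_points([(0, 0), (1, 1), (2, 0)]), np.pi)

    def test_rejects_nonfinite(self):
        with pytest.raises(GeometryError):
            PointSet(np.array([[0.0, np.nan], [1, 1], [2, 2]]))


class TestEmpiricalQuantile:
    def test_constant_data(self):
        assert empirical_quantile(np.array([5.0, 5.0, 5.0]), 0.37) == 5.0

    def test_extremes_are_min_and_max(self):
        v = np.array([1.0, 2, 3, 4, 5])
        assert empirical_quantile(v, 0.0) == 1.0
        assert empirical_quantile(v, 1.0) == 5.0

    def test_interpolated_median_of_1_to_100(self):
        v = np.arange(1.0, 101.0)
        assert empirical_quantile(v, 0.5) == pytest.approx(50.5)

    def test_matches_numpy_linear_method(self, rng):
        v = rng.normal(size=501)
        for p in (0.01, 0.25, 0.5, 0.9, 0.975):
            assert empirical_quantile(v, p) == pytest.approx(
                np.quantile(v, p), rel=1e-12
            )

    def test_empty_and_nan_rejected(self):
        with pytest.raises(GeometryError):
            empirical_quantile(np.array([]), 0.5)
        with pytest.raises(GeometryError):
            empirical_quantile(np.array([1.0, np.nan]), 0.5)


class TestDirectionalBand:
    def test_out_of_band_fraction_near_alpha(self, bvn_10k):
        # sort-and-count oracle: the band cut at the 2.5/97.5 percentiles
        # must leave about 5% of points outside
        band = directional_band(bvn_10k, 0.7, 0.05)
        n = bvn_10k.n
        assert abs(band.m_theta / n - 0.05) <= 2.0 / n
        d = signed_distances(bvn_10k, 0.7)
        assert band.m_theta == int(np.sum((d < band.B_l) | (d > band.B_u)))

    def test_symmetric_distances_give_symmetric_band(self, rng):
        d = rng.normal(size=4001)
        pts = _points(np.column_stack([np.zeros_like(d), np.r_[d]]))
        band = directional_band(pts, 0.0, 0.1)
        # distances symmetric about 0 in distribution
        assert band.B_l == pytest.approx(-band.B_u, abs=0.1)

    def test_full_range_band_has_no_outside_points(self):
        pts = _points([(0, 0), (1, 1), (2, 0), (0, 2), (3, 1)])
        band = directional_band(pts, 0.3, 1e-20)
        assert band.m_theta == 0

    def test_degenerate_distances_warn(self):
        pts = _points([(0.0, 1.0), (1.0, 1.0), (2.0, 1.0)])
        with pytest.warns(DegenerateDataWarning):
            directional_band(pts, 0.0, 0.5)


class TestRegionFromBands:
    def test_axis_aligned_slabs_make_unit_square(self, bvn_10k):
        from distfreecr.geometry import DirectionalBand

        bands = [
            DirectionalBand(theta=0.0, alpha_dir=0.05, B_l=-1, B_u=1,
                            S_theta=np.array([])),
            DirectionalBand(theta=np.pi / 2, alpha_dir=0.05, B_l=-1, B_u=1,
                            S_theta=np.array([])),
        ]
        reg = region_from_bands(bands)
        expect = {(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)}
        got = {tuple(np.round(v, 9)) for v in reg.vertices}
        assert got == expect
        assert reg.area == pytest.approx(4.0)

    def test_membership_matches_band_constraints(self, bvn_2k):
        bands = _bands(bvn_2k, 12, 0.1)
        reg = region_from_bands(bands)
        inside_poly = contains(reg, bvn_2k.points)
        d = np.column_stack(
            [signed_distances(bvn_2k, b.theta) for b in bands]
        )
        lo = np.array([b.B_l for b in bands])
        hi = np.array([b.B_u for b in bands])
        inside_bands = np.all((d >= lo) & (d <= hi), axis=1)
        # off-boundary points must agree exactly; allow the few points
        # sitting within roundoff of a boundary to differ
        margin = np.minimum((d - lo).min(axis=1), (hi - d).min(axis=1))
        clear = np.abs(margin) > 1e-9
        assert np.array_equal(inside_poly[clear], inside_bands[clear])

    def test_adjacent_crossover_identity(self):
        # two adjacent active boundaries: generic line-line intersection
        # solved independently must reproduce the polygon vertex
        theta, delta, c = 0.3, np.pi / 7, 1.25
        v = adjacent_crossover(theta, delta, c, c)
        for th, cc in ((theta, c), (theta + delta, c)):
            d = v[1] * np.cos(th) - v[0] * np.sin(th)
            assert d == pytest.approx(cc, abs=1e-12)

    def test_crossover_vertices_appear_in_regular_polygon(self):
        # equal boundary offsets in all directions -> regular 2K-gon whose
        # vertices are exactly the adjacent-boundary crossovers
        from distfreecr.geometry import DirectionalBand

        K, c = 8, 2.0
        grid = DirectionGrid.equally_spaced(K)
        bands = [
            DirectionalBand(theta=th, alpha_dir=0.05, B_l=-c, B_u=c,
                            S_theta=np.array([]))
            for th in grid.angles
        ]
        reg = region_from_bands(bands)
        assert reg.vertices.shape[0] == 2 * K
        expected = adjacent_crossover(grid.angles[0], grid.delta, c, c)
        dists = np.linalg.norm(reg.vertices - expected, axis=1)
        assert dists.min() < 1e-9

    def test_empty_intersection_raises(self):
        from distfreecr.geometry import DirectionalBand

        bands = [
            DirectionalBand(theta=0.0, alpha_dir=0.05, B_l=2, B_u=3,
                            S_theta=np.array([])),
            DirectionalBand(theta=1e-3, alpha_dir=0.05, B_l=-3, B_u=-2,
                            S_theta=np.array([])),
        ]
        with pytest.raises(GeometryError):
            region_from_bands(bands)

    def test_vertex_count_bounded_by_2K(self, bvn_2k):
        for K in (4, 16, 50):
            reg = region_from_bands(_bands(bvn_2k, K, 0.1))
            assert reg.vertices.shape[0] <= 2 * K


class TestContains:
    def test_centroid_inside_and_far_point_outside(self, bvn_2k):
        reg = region_from_bands(_bands(bvn_2k, 10, 0.1))
        assert contains(reg, reg.centroid)
        assert not contains(reg, reg.vertices.max(axis=0) + 10.0)

    def test_agrees_with_shapely_off_edge(self, bvn_2k, rng):
        from shapely.geometry import Point, Polygon

        reg = region_from_bands(_bands(bvn_2k, 14, 0.1))
        poly = Polygon(reg.vertices)
        lo, hi = reg.vertices.min(0) - 1, reg.vertices.max(0) + 1
        q = rng.uniform(lo, hi, size=(10_000, 2))
        mine = contains(reg, q)
        scale = float(np.abs(reg.vertices).max())
        for point, got in zip(q, mine):
            p = Point(point)
            if poly.exterior.distance(p) < 1e-9 * scale:
                continue  # on-edge verdicts may differ by convention
            assert got == poly.contains(p)


class TestInvariants:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10**6), K=st.sampled_from([4, 9, 24]))
    def test_convexity(self, seed, K):
        from scipy.spatial import ConvexHull

        pts = sample_bvn(SimDesign(design="normal", n=300, r_xy=0.4, seed=seed))
        reg = region_from_bands(_bands(pts, K, 0.1))
        hull = ConvexHull(reg.vertices)
        assert hull.volume == pytest.approx(reg.area, rel=1e-9)
        assert len(hull.vertices) == reg.vertices.shape[0]

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_translation_equivariance(self, seed, tx, ty):
        pts = sample_bvn(SimDesign(design="normal", n=200, r_xy=0.3, seed=seed))
        shifted = PointSet(pts.points + np.array([tx, ty]))
        r1 = region_from_bands(_bands(pts, 10, 0.1))
        r2 = region_from_bands(_bands(shifted, 10, 0.1))
        np.testing.assert_allclose(
            r2.vertices, r1.vertices + np.array([tx, ty]), atol=1e-8
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10**6), K=st.sampled_from([6, 15]))
    def test_rotation_by_grid_step_equivariance(self, seed, K):
        # rotating the data by delta maps the equally spaced line set onto
        # itself, so the region rotates rigidly by delta
        pts = sample_bvn(SimDesign(design="normal", n=200, r_xy=0.6, seed=seed))
        delta = np.pi / K
        R = np.array(
            [[np.cos(delta), -np.sin(delta)], [np.sin(delta), np.cos(delta)]]
        )
        rotated = PointSet(pts.points @ R.T)
        r1 = region_from_bands(_bands(pts, K, 0.1))
        r2 = region_from_bands(_bands(rotated, K, 0.1))
        from shapely.geometry import Polygon

        diff = Polygon(r2.vertices).symmetric_difference(
            Polygon(r1.vertices @ R.T)
        )
        assert diff.area < 1e-8 * Polygon(r2.vertices).area

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_alpha_nesting(self, seed):
        pts = sample_bvn(SimDesign(design="normal", n=400, r_xy=0.2, seed=seed))
        r_wide = region_from_bands(_bands(pts, 12, 0.05))
        r_narrow = region_from_bands(_bands(pts, 12, 0.3))
        assert np.all(contains(r_wide, r_narrow.vertices))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10**6), theta=st.floats(0.0, 3.1))
    def test_per_direction_coverage(self, seed, theta):
        pts = sample_bvn(SimDesign(design="normal", n=1000, r_xy=0.5, seed=seed))
        band = directional_band(pts, theta, 0.05)
        assert abs(band.m_theta / pts.n - 0.05) <= 2.0 / pts.n


class TestValidation:
    def test_pointset_needs_two_columns(self):
        with pytest.raises(GeometryError):
            PointSet(np.zeros((5, 3)))

    def test_region_needs_three_vertices(self):
        with pytest.raises(GeometryError):
            ConvexRegion(vertices=np.array([[0.0, 0], [1, 1]]))

    def test_grid_angles_must_be_increasing_in_range(self):
        with pytest.raises(GeometryError):
            DirectionGrid(np.array([0.5, 0.4]))
        with pytest.raises(GeometryError):
            DirectionGrid(np.array([0.0, np.pi]))
        g = DirectionGrid.equally_spaced(25)
        assert g.K == 25
        assert g.delta == pytest.approx(np.pi / 25)
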