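import itertools
import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from internesting import (
    EqualAreaFrame,
    KM_PER_DEGREE,
    LatLon,
    centroid_of_core,
    clip_to_water,
    kde_contours,
    lscv_bandwidth,
    mcp,
)
from internesting.homerange import KDEResult, kde_grid, lscv_score


class TestLSCV:
    def test_within_factor_two_of_reference_rule(self):
        rng = np.random.default_rng(10)
        xy = rng.normal(0, 1, size=(500, 2))
        (hx, hy), rescaled = lscv_bandwidth(xy)
        href = 500 ** (-1.0 / 6.0)  # normal reference rule, sigma = 1
        assert href / 2 <= hx <= href * 2
        assert href / 2 <= hy <= href * 2

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        xy = rng.normal(0, 1, size=(200, 2))
        (h1, _), _ = lscv_bandwidth(xy)
        (h2, _), _ = lscv_bandwidth(xy * 3.0)
        assert h2 == pytest.approx(3.0 * h1, rel=1e-9)

    def test_returned_h_is_local_minimizer(self):
        rng = np.random.default_rng(12)
        xy = rng.normal(0, 1, size=(300, 2))
        (h, _), _ = lscv_bandwidth(xy)
        assert lscv_score(xy, h) <= lscv_score(xy, 0.5 * h)
        assert lscv_score(xy, h) <= lscv_score(xy, 2.0 * h)

    def test_unequal_variance_triggers_rescaling(self):
        rng = np.random.default_rng(13)
        xy = rng.normal(0, 1, size=(200, 2)) * np.array([1.0, 5.0])
        (hx, hy), rescaled = lscv_bandwidth(xy)
        assert rescaled
        assert hy / hx == pytest.approx(5.0, rel=0.3)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            lscv_bandwidth(np.ones((30, 2)))


class TestKDEContours:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(14)
        xy = rng.normal(0, 1, size=(400, 2))
        gx, gy, dens = kde_grid(xy, (0.3, 0.3))
        mass = dens.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0])
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_halfnormal_hdr_area_matches_closed_form(self):
        # 50% HDR of a standard bivariate normal has area 2*pi*ln 2
        rng = np.random.default_rng(15)
        xy = rng.normal(0, 1, size=(2000, 2))
        contours, masses, _ = kde_contours(xy, (0.35, 0.35), levels=(0.50,))
        area = sum(p.area for p in contours[0.50])
        assert area == pytest.approx(2 * math.pi * math.log(2), rel=0.15)

    def test_mass_self_consistency(self):
        rng = np.random.default_rng(16)
        xy = rng.normal(0, 1, size=(1000, 2))
        _contours, masses, _ = kde_contours(xy, (0.3, 0.3), levels=(0.50, 0.95))
        assert 0.94 <= masses[0.95] <= 0.96
        assert 0.49 <= masses[0.50] <= 0.51

    def test_two_clusters_give_two_activity_centers(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, size=(150, 2))
        b = rng.normal(0, 1, size=(150, 2)) + np.array([12.0, 0.0])
        contours, _m, _ = kde_contours(np.vstack([a, b]), (0.8, 0.8), levels=(0.50,))
        assert len(contours[0.50]) == 2

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            kde_contours(np.zeros((30, 2)) + np.arange(30)[:, None], (1.0, 1.0), levels=(1.5,))

    def test_nested_contours(self):
        rng = np.random.default_rng(18)
        xy = rng.normal(0, 1, size=(800, 2))
        contours, _m, _ = kde_contours(xy, (0.3, 0.3), levels=(0.50, 0.95))
        outer = max(contours[0.95], key=lambda p: p.area)
        for p in contours[0.50]:
            assert outer.contains(p.representative_point())


class TestClipToWater:
    def test_all_water_area_unchanged(self, coast_grid):
        # frame centred ~55 km offshore; the square sits fully in water
        frame = EqualAreaFrame(LatLon(0.0, 0.5))
        sq = Polygon([(-20, -10), (0, -10), (0, 10), (-20, 10)])
        clipped, area = clip_to_water([sq], coast_grid, frame)
        assert area == pytest.approx(sq.area, rel=1e-3)

    def test_half_over_land_halves_area(self, coast_grid):
        frame = EqualAreaFrame(LatLon(0.0, 0.0))
        # square straddling the lon=0 coastline symmetrically: 20 km each side
        sq = Polygon([(-20, -10), (20, -10), (20, 10), (-20, 10)])
        _clipped, area = clip_to_water([sq], coast_grid, frame)
        cell_km = coast_grid.cell_size * KM_PER_DEGREE
        assert abs(area - sq.area / 2) <= cell_km * 20  # one cell strip along the coast

    def test_clipped_never_larger(self, coast_grid):
        frame = EqualAreaFrame(LatLon(0.0, 0.0))
        rng = np.random.default_rng(19)
        for _ in range(5):
            cx, cy = rng.uniform(-40, 40, size=2)
            sq = Polygon([(cx - 15, cy - 15), (cx + 15, cy - 15), (cx + 15, cy + 15), (cx - 15, cy + 15)])
            _c, area = clip_to_water([sq], coast_grid, frame)
            assert area <= sq.area + 1e-9


def brute_force_hull(xy: np.ndarray) -> set:
    """Hull vertices by the orientation test over all point pairs."""
    n = xy.shape[0]
    hull = set()
    for i, j in itertools.permutations(range(n), 2):
        a, b = xy[i], xy[j]
        cross = (b[0] - a[0]) * (xy[:, 1] - a[1]) - (b[1] - a[1]) * (xy[:, 0] - a[0])
        if np.all(cross >= -1e-9):
            hull.add(i)
            hull.add(j)
    return hull


class TestMCP:
    def test_unit_square_km(self):
        frame = EqualAreaFrame(LatLon(29.0, -87.0))
        corners = [frame.inverse(x, y) for x, y in [(0, 0), (1, 0), (1, 1), (0, 1)]]
        res = mcp(corners)
        assert res.area_km2 == pytest.approx(1.0, abs=1e-6)
        center = frame.inverse(0.5, 0.5)
        assert res.centroid.lat == pytest.approx(center.lat, abs=1e-6)
        assert res.centroid.lon == pytest.approx(center.lon, abs=1e-6)

    def test_hull_matches_brute_force(self):
        rng = np.random.default_rng(20)
        frame = EqualAreaFrame(LatLon(29.0, -87.0))
        xy = rng.uniform(-30, 30, size=(30, 2))
        points = [frame.inverse(x, y) for x, y in xy]
        res = mcp(points)
        hull_xy = np.array(res.hull.exterior.coords[:-1])
        expected = brute_force_hull(xy)
        # hull coordinates live in the result's own frame: reproject inputs
        px, py = res.frame.forward_xy(
            np.array([p.lat for p in points]), np.array([p.lon for p in points])
        )
        proj = np.column_stack([px, py])
        got = {int(np.argmin(np.sum((proj - v) ** 2, axis=1))) for v in hull_xy}
        assert got == expected

    def test_interior_point_changes_nothing(self):
        frame = EqualAreaFrame(LatLon(29.0, -87.0))
        pts = [frame.inverse(x, y) for x, y in [(0, 0), (10, 0), (10, 10), (0, 10)]]
        res1 = mcp(pts)
        res2 = mcp(pts + [frame.inverse(5, 5)])
        assert res2.area_km2 == pytest.approx(res1.area_km2, rel=1e-9)

    def test_collinear_degenerates_flagged(self):
        frame = EqualAreaFrame(LatLon(29.0, -87.0))
        pts = [frame.inverse(float(i), 0.0) for i in range(4)]
        res = mcp(pts)
        assert res.degenerate and res.area_km2 == 0.0
        assert res.centroid.lat == pytest.approx(29.0, abs=1e-6)


class TestCentroidOfCore:
    def _kde_with(self, polys):
        frame = EqualAreaFrame(LatLon(29.0, -87.0))
        return KDEResult(frame, (1.0, 1.0), False, {0.50: polys}, {0.50: 0.5})

    def test_single_polygon(self):
        sq = Polygon([(0, 0), (2, 0), (2, 2), (0, 2)])
        c = centroid_of_core(self._kde_with([sq]))
        frame = EqualAreaFrame(LatLon(29.0, -87.0))
        expect = frame.inverse(1.0, 1.0)
        assert (c.lat, c.lon) == pytest.approx((expect.lat, expect.lon), abs=1e-9)

    def test_largest_area_wins(self):
        big = Polygon([(0, 0), (5, 0), (5, 2), (0, 2)])  # 10 km^2
        small = Polygon([(20, 0), (23, 0), (23, 1), (20, 1)])  # 3 km^2
        c = centroid_of_core(self._kde_with([small, big]))
        frame = EqualAreaFrame(LatLon(29.0, -87.0))
        expect = frame.inverse(2.5, 1.0)
        assert c.lon == pytest.approx(expect.lon, abs=1e-9)

    def test_equal_area_tie_breaks_west(self):
        west = Polygon([(-10, 0), (-8, 0), (-8, 2), (-10, 2)])
        east = Polygon([(8, 0), (10, 0), (10, 2), (8, 2)])
        c = centroid_of_core(self._kde_with([east, west]))
        frame = EqualAreaFrame(LatLon(29.0, -87.0))
        expect = frame.inverse(-9.0, 1.0)
        assert c.lon == pytest.approx(expect.lon, abs=1e-9)

    def test_no_polygons_raises(self):
        with pytest.raises(ValueError, match="no contour"):
            centroid_of_core(self._kde_with([]))
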