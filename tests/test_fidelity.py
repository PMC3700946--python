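import datetime as dt
import math

import numpy as np
import pytest

from internesting import (
    KM_PER_DEGREE,
    LatLon,
    correlate,
    emergence_stats,
    load_fixture,
    nest_site_fidelity,
    pooled_weighted_mean,
    round_half_up,
    site_fidelity_test,
    summarize_column,
    total_distance_moved,
)
from internesting.io_formats import Emergence
from internesting.ssm import InternestingPeriod

from conftest import T0, make_track


def water_points(center: LatLon, offsets_km):
    return [
        LatLon(center.lat + dy / KM_PER_DEGREE, center.lon + dx / KM_PER_DEGREE)
        for dx, dy in offsets_km
    ]


class TestSiteFidelityTest:
    def test_tight_cluster_passes_unanimously(self, open_water_grid):
        center = LatLon(29.0, -87.0)
        rng = np.random.default_rng(30)
        # cluster radius ~1 km, but 30 steps of ~1 km path length
        pts = water_points(center, rng.normal(0, 0.5, size=(30, 2)))
        res = site_fidelity_test(pts, open_water_grid, n_rep=100, seed=1)
        assert res.passes and res.prop_null_exceeding == 1.0

    def test_ballistic_track_fails(self, open_water_grid):
        center = LatLon(28.0, -88.5)
        pts = water_points(center, [(i * 3.0, 0.0) for i in range(30)])
        res = site_fidelity_test(pts, open_water_grid, n_rep=100, seed=2)
        assert not res.passes
        assert res.prop_null_exceeding <= 0.05  # observed MSD in the upper tail

    def test_same_seed_identical_null(self, open_water_grid):
        center = LatLon(29.0, -87.0)
        rng = np.random.default_rng(31)
        pts = water_points(center, rng.normal(0, 2.0, size=(15, 2)))
        r1 = site_fidelity_test(pts, open_water_grid, n_rep=50, seed=7)
        r2 = site_fidelity_test(pts, open_water_grid, n_rep=50, seed=7)
        assert np.array_equal(r1.null_msd, r2.null_msd)

    def test_start_on_land_rejected(self, open_water_grid):
        pts = [LatLon(32.95, -87.0)] + water_points(LatLon(29, -87), [(i, 0) for i in range(12)])
        with pytest.raises(ValueError, match="outside the water domain"):
            site_fidelity_test(pts, open_water_grid, seed=0)

    def test_too_few_points_rejected(self, open_water_grid):
        with pytest.raises(ValueError, match=">= 10"):
            site_fidelity_test(water_points(LatLon(29, -87), [(0, 0)] * 5),
                               open_water_grid, seed=0)


class TestNestSiteFidelity:
    @pytest.mark.parametrize(
        "d,expected", [(3.5, True), (129.0, False), (5.0, True), (5.0001, False), (0.0, True)]
    )
    def test_five_km_rule_boundary_inclusive(self, d, expected):
        assert nest_site_fidelity(d) is expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            nest_site_fidelity(-1.0)


class TestEmergenceStats:
    def test_fixed_point_repeats(self):
        pos = LatLon(30.0, -87.0)
        evs = {
            "a": [
                Emergence("a", dt.date(2012, 6, 1), "AL", pos, "nest"),
                Emergence("a", dt.date(2012, 6, 15), "AL", pos, "nest"),
                Emergence("a", dt.date(2012, 6, 29), "AL", pos, "nest"),
            ]
        }
        s = emergence_stats(evs)
        assert s.per_turtle_intervals["a"] == [14, 14]
        assert s.per_turtle_distances["a"] == [0.0, 0.0]

    def test_pooled_count_conservation(self):
        rng = np.random.default_rng(33)
        evs = {}
        for t in range(4):
            tid = f"t{t}"
            n = int(rng.integers(1, 6))
            evs[tid] = [
                Emergence(tid, dt.date(2012, 6, 1 + 3 * i), "AL",
                          LatLon(30.0 + rng.normal(0, 0.01), -87.0), "nest")
                for i in range(n)
            ]
        s = emergence_stats(evs)
        assert s.pooled_n == sum(len(d) for d in s.per_turtle_distances.values())

    def test_table1_pooled_weighted_mean(self):
        """Per-turtle means weighted by their distance counts pool to the
        published 27.5 km over 45 emergence distances."""
        t1 = load_fixture("table1")
        rows = t1.dropna(subset=["mean_distance_km"])
        mean, n = pooled_weighted_mean(
            rows["mean_distance_km"].tolist(), rows["n_distances"].astype(int).tolist()
        )
        assert n == 45
        assert round_half_up(mean) == 27.5


class TestTotalDistanceMoved:
    def test_stationary_track_zero(self):
        track = make_track([(29.0, -87.0)] * 10, step_hours=24.0)
        period = InternestingPeriod("t1", T0.date(), T0.date() + dt.timedelta(days=9))
        tdm, _rate = total_distance_moved(track, period)
        assert tdm == 0.0

    def test_equatorial_steps_analytic(self):
        track = make_track([(0.0, 0.1 * i) for i in range(11)], step_hours=8.0)
        period = InternestingPeriod("t1", T0.date(), T0.date() + dt.timedelta(days=4))
        tdm, rate = total_distance_moved(track, period)
        assert tdm == pytest.approx(KM_PER_DEGREE, abs=1e-3)
        assert rate == pytest.approx(tdm / 4)

    def test_collinear_midpoint_invariance(self):
        track = make_track([(0.0, 0.0), (0.0, 0.2)], step_hours=8.0)
        with_mid = make_track([(0.0, 0.0), (0.0, 0.1), (0.0, 0.2)], step_hours=4.0)
        period = InternestingPeriod("t1", T0.date(), T0.date() + dt.timedelta(days=1))
        d1, _ = total_distance_moved(track, period)
        d2, _ = total_distance_moved(with_mid, period)
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_empty_period_rejected(self):
        track = make_track([(29.0, -87.0)] * 3)
        period = InternestingPeriod("t1", dt.date(2013, 1, 1), dt.date(2013, 1, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            total_distance_moved(track, period)


class TestSummaries:
    def test_table2_core_area_summary(self):
        s = summarize_column(load_fixture("table2")["area50_km2"])
        assert round_half_up(s.mean) == 61.9
        assert round_half_up(s.sd) == 28.2

    def test_table3_totals_summary(self):
        s = summarize_column(load_fixture("table3")["total_km"])
        assert round_half_up(s.mean) == 304.3
        assert round_half_up(s.sd) == 180.6

    def test_single_element_sd_flagged(self):
        s = summarize_column([5.0])
        assert s.sd is None and s.mean == 5.0

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_column([])

    def test_half_up_rounding(self):
        assert round_half_up(61.85) == 61.9
        assert round_half_up(22.825, 1) == 22.8  # hundredths digit only
        assert round_half_up(0.25, 1) == 0.3


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(34)
        x = rng.normal(size=20)
        y = 0.4 * x + rng.normal(size=20)
        r, p = correlate(x, y)
        # independent computation from the covariance definition
        rx = x - x.mean()
        ry = y - y.mean()
        r_direct = float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))
        assert r == pytest.approx(r_direct, abs=1e-12)
        t = r_direct * math.sqrt(18 / (1 - r_direct**2))
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(abs(t), 18), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
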