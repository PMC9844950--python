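"""Daily distances, eligibility, regional assignment and aggregation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from mobimetrics import (
    EstimationConfig,
    Region,
    RegionSet,
    aggregate,
    assign_region,
    country_aggregate,
    daily_distance,
    eligible,
    gate_distance,
    region_daily_mean,
    stationarity_flag,
)
from mobimetrics import metrics_core
from mobimetrics.experiments import naive_daily_distances, random_trajectories

from conftest import make_trajectory

KM_LAT = 1.0 / 110.574389  # 1 km in degrees of latitude at the equator


class TestGate:
    @pytest.mark.parametrize(
        "l,u1,u2,r,expected",
        [
            (100.0, 30.0, 30.0, 1.0, 100.0),  # above threshold: kept
            (59.9, 30.0, 30.0, 1.0, 0.0),  # just below: zeroed
            (60.0, 30.0, 30.0, 1.0, 60.0),  # boundary is inclusive (>=)
            (100.0, 30.0, 30.0, 2.0, 0.0),  # r scales the threshold
            (0.0, 5.0, 5.0, 1.0, 0.0),
        ],
    )
    def test_formula(self, l, u1, u2, r, expected):
        assert gate_distance(l, u1, u2, r) == expected


class TestStationarity:
    def test_strict_threshold(self):
        assert stationarity_flag(0.15, 0.2) == 1
        assert stationarity_flag(0.2, 0.2) == 0  # strict "<"
        assert stationarity_flag(0.0, 0.2) == 1


class TestEligibility:
    def _traj(self, n_obs, span_h, day="2020-03-11"):
        step = span_h * 3600 / max(n_obs - 1, 1)
        pts = [
            (np.datetime64(f"{day}T00:00:00") + np.timedelta64(int(i * step), "s"), 45.0, 9.0)
            for i in range(n_obs)
        ]
        return make_trajectory("a", [(str(p[0]), p[1], p[2]) for p in pts])

    def test_too_few_observations(self):
        assert not eligible(self._traj(11, 14), "2020-03-11", n=12)

    def test_enough_observations_and_span(self):
        assert eligible(self._traj(12, 13), "2020-03-11", n=12)

    def test_too_short_a_span(self):
        assert not eligible(self._traj(20, 6), "2020-03-11", n=12)

    def test_only_the_given_days_observations_count(self):
        assert not eligible(self._traj(12, 13, day="2020-03-12"), "2020-03-11", n=12)


class TestDailyDistance:
    def test_stationary_device_travels_zero(self):
        pts = [(f"2020-03-11T{h:02d}:00:00", 0.0, 9.0) for h in range(0, 24, 2)]
        assert daily_distance(make_trajectory("a", pts), "2020-03-11") == 0.0

    def test_single_one_km_hop(self):
        pts = [
            ("2020-03-11T08:00:00", 0.0, 9.0),
            ("2020-03-11T09:00:00", KM_LAT, 9.0),
            ("2020-03-11T10:00:00", KM_LAT, 9.0),
        ]
        d = daily_distance(make_trajectory("a", pts), "2020-03-11")
        assert d == pytest.approx(1.0, rel=5e-3)

    def test_cross_midnight_travel_accrues_to_the_earlier_day(self):
        pts = [
            ("2020-03-11T12:00:00", 0.0, 9.0),
            ("2020-03-11T23:50:00", 0.0, 9.0),
            ("2020-03-12T00:10:00", 2 * KM_LAT, 9.0),
            ("2020-03-12T08:00:00", 2 * KM_LAT, 9.0),
        ]
        tr = make_trajectory("a", pts)
        assert daily_distance(tr, "2020-03-11") == pytest.approx(2.0, rel=5e-3)
        assert daily_distance(tr, "2020-03-12") == 0.0

    def test_gate_zeroes_sub_uncertainty_jitter(self):
        # 30 m hop with u = 25 m on both ends: below the 50 m gate
        pts = [
            ("2020-03-11T08:00:00", 0.0, 9.0),
            ("2020-03-11T09:00:00", 0.030 * KM_LAT, 9.0),
        ]
        assert daily_distance(make_trajectory("a", pts), "2020-03-11") == 0.0

    def test_matches_naive_oracle_on_random_walks(self):
        trs = random_trajectories(60, seed=3)
        stats = metrics_core.compute_daily_stats(trs, EstimationConfig())
        table = {(r.trajectory_id, r.date): r.L_km for r in stats.itertuples()}
        for tr in trs:
            for day, ref in naive_daily_distances(tr).items():
                assert table.get((tr.trajectory_id, day), 0.0) == pytest.approx(
                    ref, rel=1e-9, abs=1e-12
                )

    def test_non_increasing_in_gate_multiplier(self):
        trs = random_trajectories(30, seed=4)
        prev = None
        for r in (1.0, 2.0, 3.0):
            stats = metrics_core.compute_daily_stats(trs, EstimationConfig(r=r))
            total = stats["L_km"].sum()
            if prev is not None:
                assert total <= prev + 1e-12
            prev = total


class TestRegionAssignment:
    def test_interior_point(self, two_region_set):
        rid = assign_region(44.7, 8.7, two_region_set)
        assert rid == "A"

    def test_boundary_counts_as_inside(self, two_region_set):
        assert assign_region(44.0, 8.0, two_region_set) == "A"

    def test_point_outside_all_regions_is_none(self, two_region_set):
        assert assign_region(20.0, -40.0, two_region_set) is None

    def test_matches_brute_force_scan(self, two_region_set):
        rng = np.random.default_rng(9)
        lats = rng.uniform(43.0, 46.0, 200)
        lons = rng.uniform(7.0, 12.0, 200)
        for lat, lon in zip(lats, lons):
            hits = [
                reg.region_id
                for reg in two_region_set.regions
                if reg.geometry.covers(Point(lon, lat))
            ]
            assert assign_region(lat, lon, two_region_set) == (hits[0] if hits else None)
            assert len(hits) <= 1  # regions are disjoint


class TestAggregation:
    def test_region_mean(self):
        assert region_daily_mean([10.0, 20.0]) == 15.0
        assert region_daily_mean([7.0]) == 7.0
        assert region_daily_mean([1, 0, 0, 1]) == 0.5

    def test_population_weighted_country_value(self, two_region_set):
        got = country_aggregate({"A": 10.0, "B": 20.0}, two_region_set)
        assert got == pytest.approx(0.75 * 10 + 0.25 * 20)

    def test_weights_renormalised_over_covered_regions(self, two_region_set):
        assert country_aggregate({"B": 20.0}, two_region_set) == 20.0

    def test_all_regions_missing_is_an_error(self, two_region_set):
        with pytest.raises(ValueError):
            country_aggregate({}, two_region_set)

    def test_invariant_to_region_relabelling(self):
        rs1 = RegionSet(
            "SYN",
            [Region("A", box(0, 0, 1, 1), 75.0), Region("B", box(2, 0, 3, 1), 25.0)],
        )
        rs2 = RegionSet(
            "SYN",
            [Region("X", box(0, 0, 1, 1), 75.0), Region("Y", box(2, 0, 3, 1), 25.0)],
        )
        v1 = country_aggregate({"A": 10.0, "B": 20.0}, rs1)
        v2 = country_aggregate({"X": 10.0, "Y": 20.0}, rs2)
        assert v1 == v2

    def test_invariant_to_splitting_a_region_with_proportional_population(self):
        rs = RegionSet(
            "SYN",
            [Region("A", box(0, 0, 1, 1), 60.0), Region("B", box(2, 0, 3, 1), 40.0)],
        )
        split = RegionSet(
            "SYN",
            [
                Region("A1", box(0, 0, 0.5, 1), 30.0),
                Region("A2", box(0.5, 0, 1, 1), 30.0),
                Region("B", box(2, 0, 3, 1), 40.0),
            ],
        )
        whole = country_aggregate({"A": 12.0, "B": 20.0}, rs)
        halves = country_aggregate({"A1": 12.0, "A2": 12.0, "B": 20.0}, split)
        assert whole == pytest.approx(halves)


def _stats_frame(rows):
    df = pd.DataFrame(
        rows, columns=["trajectory_id", "date", "region_id", "L_km", "U"]
    )
    df["date"] = pd.to_datetime(df["date"])
    df["eligible"] = True
    return df


class TestSmoothing:
    def test_q1_equals_daily_series(self, two_region_set):
        rows = [
            ("t1", "2020-03-11", "A", 10.0, 0),
            ("t2", "2020-03-11", "A", 20.0, 0),
            ("t3", "2020-03-11", "B", 5.0, 1),
            ("t1", "2020-03-12", "A", 30.0, 0),
        ]
        stats = _stats_frame(rows)
        daily = aggregate(stats, two_region_set, q=1)
        smoothed = metrics_core.smooth(stats, two_region_set, q=1)
        pd.testing.assert_frame_equal(daily, smoothed)
        assert daily.loc["2020-03-11", "m1_km"] == pytest.approx(0.75 * 15 + 0.25 * 5)

    def test_two_day_window_pools_by_device_count(self, two_region_set):
        # counts (1, 3), daily region means (10, 20): pooled = 70/4 = 17.5
        rows = [("t1", "2020-03-11", "A", 10.0, 0)] + [
            (f"s{i}", "2020-03-12", "A", 20.0, 0) for i in range(3)
        ]
        out = aggregate(_stats_frame(rows), two_region_set, q=2)
        assert out.loc["2020-03-12", "m1_km"] == pytest.approx(17.5)
        assert np.isnan(out.loc["2020-03-11", "m1_km"])  # first q-1 days missing

    def test_constant_series_invariant_under_any_window(self, two_region_set):
        rows = [
            (f"t{d}{i}", f"2020-03-{11 + d:02d}", "A", 4.0, 0)
            for d in range(10)
            for i in range(3)
        ]
        stats = _stats_frame(rows)
        for q in (1, 7):
            out = aggregate(stats, two_region_set, q=q)
            assert np.allclose(out["m1_km"].dropna(), 4.0)

    def test_m2_bounds_and_m1_nonnegative(self, small_sim):
        stats = metrics_core.compute_daily_stats(
            small_sim.trajectories, EstimationConfig(), regions=small_sim.region_set
        )
        for q in (1, 7):
            out = aggregate(stats, small_sim.region_set, q=q).dropna()
            assert (out["m1_km"] >= 0).all()
            assert out["m2_frac"].between(0, 1).all()


def test_ineligible_and_unassigned_devices_are_excluded(two_region_set):
    rows = [
        ("in", "2020-03-11", "A", 10.0, 0),
        ("out", "2020-03-11", None, 99.0, 0),
    ]
    df = _stats_frame(rows)
    df.loc[df["trajectory_id"] == "out", "region_id"] = None
    ineligible = _stats_frame([("lazy", "2020-03-11", "A", 50.0, 0)])
    ineligible["eligible"] = False
    stats = pd.concat([df, ineligible], ignore_index=True)
    out = aggregate(stats, two_region_set, q=1)
    assert out.loc["2020-03-11", "m1_km"] == 10.0
    assert out.loc["2020-03-11", "n"] == 1  # N counts eligible+assigned only
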