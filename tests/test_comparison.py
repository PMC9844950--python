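"""Correlation, lag profiles, penetration and the sensitivity grid."""

import numpy as np
import pandas as pd
import pytest

from mobimetrics import (
    EstimationConfig,
    average_penetration,
    fit_beta_regression,
    pearson,
    read_cmr,
    sensitivity_grid,
    shift_profile,
    simulate_index,
)
from mobimetrics import comparison, metrics_core, synthetic


def _series(values, start="2020-03-11"):
    return pd.Series(values, index=pd.date_range(start, periods=len(values), freq="D"), dtype=float)


class TestPearson:
    def test_self_correlation_is_one(self):
        a = _series([1, 3, 2, 5, 4])
        assert pearson(a, a) == pytest.approx(1.0)

    def test_negation_flips_the_sign(self):
        a = _series([1, 3, 2, 5, 4])
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_overlap_only(self):
        a = _series([1, 2, 3, 4, 5, 6])
        b = _series([9, 2, 4, 6, 8, 1], start="2020-03-13")  # offset by 2 days
        j = pd.concat([a, b], axis=1, join="inner").dropna()
        expect = np.corrcoef(j.iloc[:, 0], j.iloc[:, 1])[0, 1]
        assert pearson(a, b) == pytest.approx(expect)

    def test_constant_series_is_missing_with_warning(self):
        a = _series([1, 1, 1, 1])
        b = _series([1, 2, 3, 4])
        with pytest.warns(UserWarning):
            assert np.isnan(pearson(a, b))

    def test_too_little_overlap_is_missing(self):
        a = _series([1, 2])
        with pytest.warns(UserWarning):
            assert np.isnan(pearson(a, a * 2))

    def test_independent_white_noise_is_near_zero(self):
        misses = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = _series(rng.standard_normal(1000))
            b = _series(rng.standard_normal(1000))
            misses += abs(pearson(a, b)) >= 0.1
        assert misses <= 1


class TestShiftProfile:
    def test_identical_series_peak_at_zero(self):
        rng = np.random.default_rng(0)
        a = _series(np.cumsum(rng.standard_normal(200)))
        prof = shift_profile(a, a)
        assert len(prof) == 29
        assert prof.abs().le(1 + 1e-12).all()
        assert int(prof.idxmax()) == 0

    def test_recovers_a_constructed_positive_lag(self):
        rng = np.random.default_rng(1)
        a = _series(np.cumsum(rng.standard_normal(300)))
        b = a.copy()
        b.index = b.index + pd.Timedelta(days=7)  # b trails a by 7 days
        prof = shift_profile(a, b)
        assert int(prof.idxmax()) == 7


class TestPenetration:
    def test_constant_counts(self):
        counts = _series([100.0] * 30)
        assert average_penetration(counts, 1_000_000) == pytest.approx(1e-4)

    def test_mean_then_divide(self):
        assert average_penetration(_series([50.0, 150.0]), 1e6) == pytest.approx(1e-4)

    def test_zero_counts_degenerate(self):
        assert average_penetration(_series([0.0, 0.0]), 1e6) == 0.0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            average_penetration(_series([1.0]), 0)
        with pytest.raises(ValueError):
            average_penetration(_series([]), 1e6)


class TestBetaRegression:
    def test_recovers_a_strong_monotone_relationship(self):
        rng = np.random.default_rng(2)
        pi = 10.0 ** np.linspace(-5, -3, 17)
        mu = 1 / (1 + np.exp(-(3.0 + 0.5 * np.log10(pi))))
        y = rng.beta(mu * 4000, (1 - mu) * 4000)  # high precision: near-noiseless
        fit = fit_beta_regression(y, pi)
        assert fit.beta1 == pytest.approx(0.5, abs=0.1)
        assert fit.pseudo_r2 > 0.95
        assert fit.f_pvalue < 1e-4
        # logit-link monotonicity of the fitted means
        order = np.argsort(pi)
        assert np.all(np.diff(fit.mu[order]) > 0)

    def test_rho_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_regression([0.5, 1.2, 0.3], [1e-4, 1e-4, 1e-4])

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            fit_beta_regression([0.5, 0.6], [1e-4, 1e-3])

    def test_boundary_values_are_shrunk_onto_the_open_interval(self):
        rng = np.random.default_rng(3)
        pi = 10.0 ** np.linspace(-5, -3, 10)
        y = rng.uniform(0.3, 0.9, 10)
        y[0], y[-1] = 0.0, 1.0
        fit = fit_beta_regression(y, pi)  # must not error out
        assert np.isfinite(fit.beta1) and fit.phi > 0


class TestSimulatedIndex:
    def test_zero_noise_identity_map_correlates_perfectly(self):
        s = _series(np.linspace(5, 10, 60))
        idx = simulate_index(s, noise_sd=0.0)
        assert pearson(s, idx) == pytest.approx(1.0)

    def test_negation_yields_perfect_anticorrelation(self):
        s = _series(np.linspace(5, 10, 60))
        idx = simulate_index(s, noise_sd=0.0, scale=-1.0)
        assert pearson(s, idx) == pytest.approx(-1.0)

    def test_noise_attenuates_towards_a_target_correlation(self):
        # rho = 1/sqrt(1 + sigma^2/var(signal)); pick sigma for rho ~ 0.8
        rng = np.random.default_rng(4)
        n = 900
        signal = _series(10 + 3 * np.sin(np.arange(n) / 20) + rng.standard_normal(n))
        pct = 100 * (signal - signal.iloc[:14].mean()) / signal.iloc[:14].mean()
        sigma = float(pct.std() * np.sqrt(1 / 0.8**2 - 1))
        hits = 0
        for seed in range(20):
            idx = simulate_index(signal, noise_sd=sigma, seed=seed)
            hits += 0.7 <= pearson(signal, idx) <= 0.9
        assert hits >= 18

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_index(_series([0.0] * 30))


def test_read_cmr_keeps_country_level_rows_only(tmp_path):
    sub = pd.Series([1.0] * 5, index=pd.date_range("2020-03-11", periods=5))
    synthetic.write_cmr_csv({"SYN": {"transit_stations": sub, "residential": -sub}}, tmp_path / "cmr.csv")
    # append a sub-regional row that must be ignored
    with open(tmp_path / "cmr.csv", "a") as fh:
        fh.write("SYN,SYN,Region 1,,,,,,2020-03-11,5,5,5,5,5,5\n")
    cmr = read_cmr(tmp_path / "cmr.csv")
    assert set(cmr["index_name"]) == {"transit_stations", "residential"}
    assert len(cmr[cmr["index_name"] == "transit_stations"]) == 5
    got = comparison.index_series(cmr, "SYN", "transit_stations")
    assert (got == 1.0).all()


@pytest.fixture(scope="module")
def grid_inputs():
    cfg = synthetic.SimulationConfig(
        seed=11,
        n_days=30,
        regions=(
            synthetic.RegionSpec("A", 8.0, 44.0, 1.5, 1.5, 2_000_000, 30),
            synthetic.RegionSpec("B", 10.0, 44.0, 1.5, 1.5, 1_000_000, 15),
        ),
    )
    sim = synthetic.simulate_trajectories(cfg)
    transit = simulate_index(sim.true_series["m1_km"], noise_sd=2.0, seed=1)
    residential = simulate_index(sim.true_series["m2_frac"], noise_sd=2.0, seed=2)
    return sim, transit, residential


class TestSensitivityGrid:
    def test_grid_shape_and_bounds(self, grid_inputs):
        sim, transit, residential = grid_inputs
        grid = sensitivity_grid(
            sim.trajectories, sim.region_set, transit, residential,
            n_grid=(6, 12), r_grid=(1.0, 2.0), z_grid=(0.1, 0.2),
        )
        assert len(grid) == 8
        assert grid["rho1_abs"].between(0, 1).all()
        assert grid["rho2_abs"].between(0, 1).all()
        assert grid["argmax_rho1"].any() and grid["argmax_rho2"].any()

    def test_z_only_affects_the_stationarity_metric(self, grid_inputs):
        sim, transit, residential = grid_inputs
        grid = sensitivity_grid(
            sim.trajectories, sim.region_set, transit, residential,
            n_grid=(12,), r_grid=(1.0,), z_grid=(0.1, 0.2, 0.4),
        )
        assert grid["rho1_abs"].nunique() == 1  # z never touches M1
        assert grid["rho2_abs"].nunique() > 1

    def test_total_distance_non_increasing_in_r(self, grid_inputs):
        sim, _, _ = grid_inputs
        totals = []
        for r in (1.0, 2.0, 3.0):
            stats = metrics_core.compute_daily_stats(
                sim.trajectories, EstimationConfig(r=r), regions=sim.region_set
            )
            totals.append(stats["L_km"].sum())
        assert totals[0] >= totals[1] >= totals[2]


def test_smoothing_raises_index_correlations(small_sim):
    """Daily sampling noise attenuates correlations; a 7-day moving average
    recovers them (the no-smoothing vs 7-day contrast)."""
    stats = metrics_core.compute_daily_stats(
        small_sim.trajectories, EstimationConfig(), regions=small_sim.region_set
    )
    idx = simulate_index(small_sim.true_series["m1_km"], noise_sd=4.0, seed=5)
    rhos = {}
    for q in (1, 7):
        agg = metrics_core.aggregate(stats, small_sim.region_set, q=q)
        idx_s = idx.rolling(q, min_periods=q).mean() if q > 1 else idx
        rhos[q] = abs(pearson(agg["m1_km"], idx_s))
    assert rhos[7] > rhos[1]
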