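"""Validation experiments shared by the test suite and the acceptance script.

Each function runs a self-contained Monte-Carlo or fixture experiment
against the package's own estimators and returns plain numbers. Problem
sizes are chosen so the full set runs in minutes on one CPU; the methods
note records the sizes used.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import comparison, metrics_core, synthetic, uncertainty
from .metrics_core import EstimationConfig
from .trajectory_io import Trajectory

# ---------------------------------------------------------------------------
# naive reference implementation of the daily-distance estimator
# ---------------------------------------------------------------------------


def naive_daily_distances(trajectory: Trajectory, r: float = 1.0) -> dict:
    """Reference daily travelled distance: an explicit Python loop over
    consecutive observation pairs, attributing each gated geodesic segment
    to the calendar day of its earlier endpoint. Kept deliberately naive
    (scalar calls, no vectorisation) to validate the pipeline implementation.
    """
    totals: dict = {}
    for i in range(len(trajectory) - 1):
        l = metrics_core.geodesic_distance(
            float(trajectory.lat[i]),
            float(trajectory.lon[i]),
            float(trajectory.lat[i + 1]),
            float(trajectory.lon[i + 1]),
        )
        l_hat = metrics_core.gate_distance(l, float(trajectory.u[i]), float(trajectory.u[i + 1]), r)
        day = pd.Timestamp(trajectory.t[i]).normalize()
        totals[day] = totals.get(day, 0.0) + l_hat / 1000.0
    return totals


def random_trajectories(n: int, seed: int) -> list[Trajectory]:
    """Handcrafted random-walk trajectories spanning several days, with
    cross-midnight pairs, occasional zero steps and gate-boundary steps."""
    rng = np.random.default_rng(seed)
    out = []
    t0 = np.datetime64("2020-03-11T00:00:00", "s")
    for k in range(n):
        m = int(rng.integers(2, 40))
        gaps = rng.integers(20 * 60, 8 * 3600, size=m - 1)  # 20 min .. 8 h
        t = t0 + np.concatenate([[0], np.cumsum(gaps)]).astype("timedelta64[s]")
        t = t + np.timedelta64(int(rng.integers(0, 86400)), "s")
        lat0, lon0 = rng.uniform(-60, 60), rng.uniform(-170, 170)
        step_m = rng.choice([0.0, 30.0, 50.0, 200.0, 2000.0], size=m, p=[0.2, 0.2, 0.1, 0.2, 0.3])
        bear = rng.uniform(0, 2 * math.pi, size=m)
        dlat = np.cumsum(step_m * np.cos(bear)) / 111_319.5
        dlon = np.cumsum(step_m * np.sin(bear)) / (111_319.5 * math.cos(math.radians(lat0)))
        out.append(
            Trajectory(
                trajectory_id=f"T{k:05d}",
                lat=lat0 + dlat,
                lon=lon0 + dlon,
                u=rng.choice([5.0, 25.0, 50.0], size=m),
                t=t,
                country="SYN",
            )
        )
    return out


def oracle_equivalence(n_trajectories: int = 1000, seed: int = 11) -> float:
    """Maximum relative disagreement between the pipeline's per-day
    distances and the naive reference over random trajectories."""
    trs = random_trajectories(n_trajectories, seed)
    stats = metrics_core.compute_daily_stats(trs, EstimationConfig())
    got = {(row.trajectory_id, row.date): row.L_km for row in stats.itertuples()}
    worst = 0.0
    for tr in trs:
        for day, ref in naive_daily_distances(tr).items():
            val = got.get((tr.trajectory_id, day), 0.0)
            denom = max(abs(ref), 1e-12)
            worst = max(worst, abs(val - ref) / denom)
    return worst


# ---------------------------------------------------------------------------
# bootstrap coverage
# ---------------------------------------------------------------------------

_COVERAGE_REGIONS = (
    synthetic.RegionSpec(
        "A", 8.0, 44.0, population=4_000_000, n_users=100,
        movement=synthetic.MovementModel(p_stay=0.25, trip_meanlog=math.log(9.0), trip_sdlog=0.5, p_missing_day=0.0),
    ),
    synthetic.RegionSpec(
        "B", 10.0, 44.0, population=2_000_000, n_users=60,
        movement=synthetic.MovementModel(p_stay=0.35, trip_meanlog=math.log(7.0), trip_sdlog=0.5, p_missing_day=0.0),
    ),
    synthetic.RegionSpec(
        "C", 8.0, 42.0, population=1_000_000, n_users=40,
        movement=synthetic.MovementModel(p_stay=0.45, trip_meanlog=math.log(5.0), trip_sdlog=0.5, p_missing_day=0.0),
    ),
)


def _true_weighted_metrics(regions, z: float = 0.2) -> tuple[float, float]:
    """Analytic population-weighted expectations of the per-device daily
    distance and stationarity flag (the coverage estimand)."""
    pops = np.array([r.population for r in regions])
    w = pops / pops.sum()
    m1 = m2 = 0.0
    for wc, spec in zip(w, regions):
        exp = synthetic.true_expected_metrics(spec.movement, np.ones(1), z=z)
        m1 += wc * float(exp["m1_km"].iloc[0])
        m2 += wc * float(exp["m2_frac"].iloc[0])
    return m1, m2


def bootstrap_coverage(n_datasets: int = 500, B: int = 1000, seed: int = 0) -> dict:
    """Empirical coverage of the 95% stratified percentile CI.

    Each dataset is one day of per-device values from three regions whose
    user counts are deliberately NOT proportional to population (app
    oversampling), drawn from region-specific movement models; the
    estimand is the analytic population-weighted mean.
    """
    regions = _COVERAGE_REGIONS
    cfg = synthetic.SimulationConfig(seed=seed, n_days=1, regions=regions, mobility=np.ones(1))
    rs = synthetic.build_region_set(cfg)
    true_m1, true_m2 = _true_weighted_metrics(regions)
    rng = np.random.default_rng(seed)
    bcfg = uncertainty.BootstrapConfig(B=B, alpha=5.0, seed=seed)

    hit1 = hit2 = 0
    for _ in range(n_datasets):
        dev = synthetic.simulate_device_days(cfg, rng=rng)
        region_values = {
            rid: (g["L_km"].to_numpy(float), g["U"].to_numpy(float))
            for rid, g in dev.groupby("region_id")
        }
        ci = uncertainty.bootstrap_aggregate_ci(region_values, rs, bcfg, rng=rng)
        hit1 += ci["m1_low"] <= true_m1 <= ci["m1_high"]
        hit2 += ci["m2_low"] <= true_m2 <= ci["m2_high"]
    return {
        "coverage_m1": hit1 / n_datasets,
        "coverage_m2": hit2 / n_datasets,
        "true_m1": true_m1,
        "true_m2": true_m2,
        "n_datasets": n_datasets,
    }


# ---------------------------------------------------------------------------
# beta-regression recovery and null calibration
# ---------------------------------------------------------------------------


def beta_recovery(
    n_reps: int = 200,
    beta0: float = 3.0,
    beta1: float = 0.5,
    phi: float = 20.0,
    n_countries: int = 17,
    seed: int = 0,
) -> dict:
    """Simulation-based recovery of the beta-regression parameters.

    Penetrations span 1e-5..1e-3 (the observed range); |rho| is drawn from
    Beta(mu_i, phi) with logit(mu_i) = beta0 + beta1*log10(pi_i). Reports
    the mean estimates, their Monte-Carlo standard errors, and the z-scores
    of the mean error.
    """
    rng = np.random.default_rng(seed)
    log10pi = np.linspace(-5, -3, n_countries)
    pi = 10.0**log10pi
    eta = beta0 + beta1 * log10pi
    mu = 1 / (1 + np.exp(-eta))
    b0s, b1s, phis = [], [], []
    for _ in range(n_reps):
        y = rng.beta(mu * phi, (1 - mu) * phi)
        fit = comparison.fit_beta_regression(y, pi)
        b0s.append(fit.beta0)
        b1s.append(fit.beta1)
        phis.append(fit.phi)
    b0s, b1s = np.array(b0s), np.array(b1s)
    return {
        "beta0_mean": float(b0s.mean()),
        "beta1_mean": float(b1s.mean()),
        "phi_mean": float(np.mean(phis)),
        "beta0_z": float((b0s.mean() - beta0) / (b0s.std(ddof=1) / math.sqrt(n_reps))),
        "beta1_z": float((b1s.mean() - beta1) / (b1s.std(ddof=1) / math.sqrt(n_reps))),
        "beta0_true": beta0,
        "beta1_true": beta1,
        "n_reps": n_reps,
    }


def beta_null_rejection(
    n_reps: int = 200,
    beta0: float = 1.0,
    phi: float = 20.0,
    n_countries: int = 17,
    level: float = 0.05,
    seed: int = 1,
) -> dict:
    """Rejection rate of the slope F-test when the true slope is zero."""
    rng = np.random.default_rng(seed)
    pi = 10.0 ** np.linspace(-5, -3, n_countries)
    mu = 1 / (1 + np.exp(-beta0))
    rej = 0
    for _ in range(n_reps):
        y = rng.beta(mu * phi, (1 - mu) * phi, size=n_countries)
        fit = comparison.fit_beta_regression(y, pi)
        rej += fit.f_pvalue < level
    return {"rejection_rate": rej / n_reps, "level": level, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# lag recovery
# ---------------------------------------------------------------------------


def lag_recovery(n_runs: int = 100, lag: int = 7, n_days: int = 200, seed: int = 0) -> dict:
    """Fraction of runs in which the time-shifted correlation profile puts
    its argmax at the constructed lag (index delayed by +7 days)."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2020-03-11", periods=n_days + lag, freq="D")
    hits = 0
    for _ in range(n_runs):
        base = synthetic.covid_like_profile(n_days + lag) * 10
        a = pd.Series(base + 0.5 * rng.standard_normal(n_days + lag), index=dates)
        b = a.copy()
        b.index = b.index + pd.Timedelta(days=lag)  # b reproduces a, `lag` days late
        b = b + 0.2 * rng.standard_normal(len(b))
        prof = comparison.shift_profile(a, b, max_lag=14)
        hits += int(prof.idxmax()) == lag
    return {"argmax_hit_rate": hits / n_runs, "lag": lag, "n_runs": n_runs}


def weekly_cycle_local_maxima(n_days: int = 400, seed: int = 0) -> list[int]:
    """Shifts at which the profile of two series sharing a weekly cycle and
    an aligned trend has local maxima (expected: multiples of 7)."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2020-03-11", periods=n_days, freq="D")
    d = np.arange(n_days)
    cycle = np.where(d % 7 >= 5, -3.0, 1.0)
    trend = synthetic.covid_like_profile(n_days, weekend_factor=1.0) * 5
    a = pd.Series(trend + cycle + 0.3 * rng.standard_normal(n_days), index=dates)
    b = pd.Series(trend + cycle + 0.3 * rng.standard_normal(n_days), index=dates)
    prof = comparison.shift_profile(a, b, max_lag=14)
    vals = prof.to_numpy()
    maxima = [
        int(prof.index[i])
        for i in range(len(vals))
        if (i == 0 or vals[i] > vals[i - 1]) and (i == len(vals) - 1 or vals[i] > vals[i + 1])
    ]
    return maxima


# ---------------------------------------------------------------------------
# penetration transition
# ---------------------------------------------------------------------------

PENETRATIONS = 10.0 ** np.array([-5.5, -5.0, -4.5, -4.0, -3.5, -3.0])


def penetration_transition(
    n_reps: int = 20,
    n_days: int = 120,
    total_population: float = 1_000_000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation between the estimated and the ground-truth country M1 as
    a function of data-set penetration.

    A dense synthetic country (three regions, lockdown-dip mobility
    profile) is subsampled so the average daily number of contributing
    devices divided by population equals each target penetration; the
    estimate uses the package's stratified aggregation. Returns per-
    penetration median (and quartile) correlations over replicates.
    """
    pop_shares = np.array([0.5, 0.3, 0.2])
    base_regions = [
        synthetic.RegionSpec(f"R{i}", 8.0 + 2 * i, 44.0, population=s * total_population, n_users=0)
        for i, s in enumerate(pop_shares)
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for pi in PENETRATIONS:
        n_total = max(int(round(pi * total_population)), 2)
        n_by_region = np.maximum(np.round(pop_shares * n_total).astype(int), 1)
        regions = tuple(
            synthetic.RegionSpec(r.region_id, r.lon0, r.lat0, r.width, r.height, r.population, int(n))
            for r, n in zip(base_regions, n_by_region)
        )
        for rep in range(n_reps):
            cfg = synthetic.SimulationConfig(
                seed=int(rng.integers(2**31 - 1)), n_days=n_days, regions=regions
            )
            rs = synthetic.build_region_set(cfg)
            dev = synthetic.simulate_device_days(cfg, rng=rng)
            est = metrics_core.aggregate(dev, rs, q=1)
            truth = _analytic_true_series(cfg, rs)
            rho = comparison.pearson(est["m1_km"], truth["m1_km"])
            rows.append((pi, rep, rho))
    df = pd.DataFrame(rows, columns=["penetration", "rep", "rho"])
    out = df.groupby("penetration")["rho"].median().reset_index()
    out.columns = ["penetration", "median_rho"]
    return out


def _analytic_true_series(cfg: synthetic.SimulationConfig, rs) -> pd.DataFrame:
    """Population-weighted expected country series (the dense-population
    limit of the ground truth)."""
    mobility = cfg.profile()
    w = rs.weights
    parts = []
    for spec in cfg.regions:
        model = spec.movement or cfg.movement
        exp = synthetic.true_expected_metrics(model, mobility)
        parts.append(exp * w[spec.region_id])
    tot = sum(parts)
    tot.index = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")
    return tot
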