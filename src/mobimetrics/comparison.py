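"""Comparison of mobility metrics with external mobility-index series.

The mobility metrics and Google-style Community Mobility Report (CMR)
indices do not share units — the metrics are km and percent-stationary,
the indices percent change in visits from a baseline — but all derive from
smartphone trajectories, so their *linear correlation* measures shared
information content. M1 is compared with the transit-stations, parks and
retail-and-recreation indices; M2 with residential and workplaces (the
latter correlating negatively).

Three diagnostics are built on that correlation:

* time-shifted correlation profiles over lags of -14..+14 days (a weekly
  cycle shows up as local maxima at multiples of 7);
* a beta regression of |rho| on log10 of the average data-set penetration
  (mean daily trajectories / population), which locates the penetration
  needed for high agreement with the external product;
* a sensitivity grid over the estimator's tunables (n, r, z).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from . import metrics_core
from .metrics_core import EstimationConfig, RegionSet

logger = logging.getLogger(__name__)

CMR_INDEX_NAMES = (
    "retail_and_recreation",
    "grocery_and_pharmacy",
    "parks",
    "transit_stations",
    "workplaces",
    "residential",
)

# index pairings actually correlated (grocery_and_pharmacy is parsed but unused)
M1_INDICES = ("transit_stations", "parks", "retail_and_recreation")
M2_INDICES = ("residential", "workplaces")

MIN_OVERLAP_DAYS = 3


def read_cmr(path) -> pd.DataFrame:
    """Country-level rows of a CMR-dialect CSV as a tidy frame.

    Country-level rows are those with an empty ``sub_region_1``. Returns
    columns country, date, index_name, value.
    """
    df = pd.read_csv(path, dtype={"country_region_code": str}, keep_default_na=False)
    if "sub_region_1" in df.columns:
        df = df[df["sub_region_1"].astype(str).str.strip() == ""]
    long = []
    for name in CMR_INDEX_NAMES:
        col = f"{name}_percent_change_from_baseline"
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        long.append(
            pd.DataFrame(
                {
                    "country": df["country_region_code"],
                    "date": pd.to_datetime(df["date"]),
                    "index_name": name,
                    "value": vals,
                }
            )
        )
    out = pd.concat(long, ignore_index=True).dropna(subset=["value"])
    return out


def index_series(cmr: pd.DataFrame, country: str, index_name: str) -> pd.Series:
    sub = cmr[(cmr["country"] == country) & (cmr["index_name"] == index_name)]
    s = sub.set_index("date")["value"].sort_index()
    s.name = index_name
    return s


def pearson(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation over the two series' common non-missing dates.

    Returns NaN (with a warning) when fewer than 3 days overlap or either
    series is constant on the overlap.
    """
    j = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(j) < MIN_OVERLAP_DAYS:
        warnings.warn("fewer than 3 overlapping days; correlation undefined")
        return float("nan")
    x, y = j.iloc[:, 0].to_numpy(float), j.iloc[:, 1].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series on the overlap; correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def shift_profile(a: pd.Series, b: pd.Series, max_lag: int = 14) -> pd.Series:
    """Correlation of ``a(t)`` with ``b(t + delta)`` for integer day lags
    delta in [-max_lag, +max_lag].

    Positive delta means the second series (typically the external index)
    is delayed relative to the first: a series ``b`` that reproduces ``a``
    seven days late has its profile argmax at delta = +7.
    """
    out = {}
    for delta in range(-max_lag, max_lag + 1):
        shifted = b.copy()
        shifted.index = shifted.index - pd.Timedelta(days=delta)
        out[delta] = pearson(a, shifted)
    prof = pd.Series(out, name="rho")
    prof.index.name = "shift_days"
    return prof


def average_penetration(daily_counts: pd.Series, population: float) -> float:
    """Mean daily contributing trajectories divided by country population."""
    if population <= 0:
        raise ValueError("population must be positive")
    if len(daily_counts) == 0:
        raise ValueError("need at least one day of counts")
    pi = float(np.asarray(daily_counts, dtype=float).mean() / population)
    if pi == 0:
        logger.warning("zero trajectories throughout; penetration degenerate at 0")
    return pi


@dataclass
class PenetrationFit:
    """Beta regression of |rho| on log10(penetration), logit link."""

    pairs: pd.DataFrame  # country, rho_abs, penetration
    beta0: float
    beta1: float
    phi: float
    mu: np.ndarray  # fitted means, data order
    pseudo_r2: float
    f_pvalue: float
    results: object = None  # statsmodels results, for diagnostics


def _shrink_boundaries(rho_abs: np.ndarray) -> np.ndarray:
    """Open-interval adjustment (x*(N-1)+0.5)/N applied when any value
    sits on the closed boundary {0, 1} of the beta support."""
    rho_abs = np.asarray(rho_abs, dtype=float)
    if ((rho_abs <= 0) | (rho_abs >= 1)).any():
        n = len(rho_abs)
        logger.info("shrinking %d boundary |rho| values onto (0,1)", int(((rho_abs <= 0) | (rho_abs >= 1)).sum()))
        return (rho_abs * (n - 1) + 0.5) / n
    return rho_abs


def fit_beta_regression(rho_abs, penetration) -> PenetrationFit:
    """ML beta regression |rho| ~ Beta(mu, phi), logit(mu) = b0 + b1*log10(pi).

    Returns coefficients, the precision phi, fitted means, the pseudo
    coefficient of determination corr(|rho|, fitted)^2, and the p-value of
    a Wald F-test of the slope against the intercept-only model.
    """
    rho_abs = np.asarray(rho_abs, dtype=float)
    pi = np.asarray(penetration, dtype=float)
    if len(rho_abs) < 3:
        raise ValueError("need at least 3 (rho, penetration) pairs")
    if ((rho_abs < 0) | (rho_abs > 1)).any():
        raise ValueError("|rho| values must lie in [0, 1]")
    if (pi <= 0).any():
        raise ValueError("penetrations must be positive")
    y = _shrink_boundaries(rho_abs)
    exog = sm.add_constant(np.log10(pi))
    model = BetaModel(y, exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"beta regression did not converge: {res.mle_retvals}")
    mu = np.asarray(res.predict())
    if np.std(mu) == 0 or np.std(rho_abs) == 0:
        pseudo_r2 = 1.0 if np.allclose(mu, rho_abs) else 0.0
    else:
        pseudo_r2 = float(np.corrcoef(rho_abs, mu)[0, 1] ** 2)
    ftest = res.f_test("x1 = 0")
    return PenetrationFit(
        pairs=pd.DataFrame({"rho_abs": rho_abs, "penetration": pi}),
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        phi=float(np.exp(res.params[-1])),  # precision is log-linked
        mu=mu,
        pseudo_r2=pseudo_r2,
        f_pvalue=float(ftest.pvalue),
        results=res,
    )


# ---------------------------------------------------------------------------
# sensitivity grid over the estimator's tunables
# ---------------------------------------------------------------------------

SENSITIVITY_N = (3, 6, 9, 12, 15)
SENSITIVITY_R = (1.0, 2.0, 3.0)
SENSITIVITY_Z = (0.1, 0.2, 0.3, 0.4)


def sensitivity_grid(
    trajectories,
    regions: RegionSet,
    index_transit: pd.Series,
    index_residential: pd.Series,
    n_grid=SENSITIVITY_N,
    r_grid=SENSITIVITY_R,
    z_grid=SENSITIVITY_Z,
) -> pd.DataFrame:
    """Unsmoothed M1/M2 recomputed for every (n, r, z); correlations
    (without sign) of M1 with the transit index and M2 with the
    residential index. Returns the full grid plus argmax flags.

    The device-day table depends on (n, r) only, and z only re-thresholds
    the stored daily distances, so the grid costs len(n)*len(r) passes.
    """
    rows = []
    for n, r in itertools.product(n_grid, r_grid):
        cfg = EstimationConfig(n=n, r=r)
        stats = metrics_core.compute_daily_stats(trajectories, cfg, regions=regions)
        for z in z_grid:
            stats_z = metrics_core.restate_stationarity(stats, z)
            agg = metrics_core.aggregate(stats_z, regions, q=1)
            rho1 = pearson(agg["m1_km"], index_transit)
            rho2 = pearson(agg["m2_frac"], index_residential)
            rows.append((n, r, z, abs(rho1), abs(rho2)))
    grid = pd.DataFrame(rows, columns=["n", "r", "z", "rho1_abs", "rho2_abs"])
    grid["argmax_rho1"] = grid["rho1_abs"] == grid["rho1_abs"].max()
    grid["argmax_rho2"] = grid["rho2_abs"] == grid["rho2_abs"].max()
    return grid
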