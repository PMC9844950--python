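"""Stratified non-parametric bootstrap intervals for the daily metrics.

Device-days are resampled with replacement *within each region*, at the
region's own sample size, and the population-weighted country aggregate is
recomputed per iteration; the interval is the empirical alpha/2 and
1-alpha/2 percentile of the B aggregates (linear interpolation between
order statistics). Stratifying by region keeps the resampling faithful to
the estimator: regional sample sizes, and hence the weighting, are part of
the design, not noise.

For a q-day smoothed estimate the resampling pool is the q-day pooled
window of device-days, which yields intervals of the correct (narrower)
width for the pooled estimator.

By default one shared resampling of device indices drives both the M1 and
M2 aggregates (devices come with both their values), preserving their
joint structure; ``joint_resampling=False`` resamples the two values
independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .metrics_core import RegionSet, _eligible_assigned

__all__ = ["BootstrapConfig", "bootstrap_aggregate_ci", "bootstrap_series"]


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 1000
    alpha: float = 5.0  # percent; 5 -> 95% intervals
    seed: int = 0
    joint_resampling: bool = True

    def __post_init__(self):
        if self.B < 2 or not (0 < self.alpha < 100):
            raise ValueError(f"invalid bootstrap config: {self}")


def bootstrap_aggregate_ci(
    region_values: Mapping[str, tuple[np.ndarray, np.ndarray]],
    regions: RegionSet,
    cfg: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Percentile CI of the weighted M1/M2 aggregate for one day/window.

    ``region_values`` maps region_id -> (L values, U values) of that
    region's device-days. Regions are processed in sorted id order so a
    fixed seed gives bit-identical bounds. Returns m1_low/m1_high/
    m2_low/m2_high (M2 on the fraction scale).
    """
    if not region_values or all(len(v[0]) == 0 for v in region_values.values()):
        raise ValueError("bootstrap needs at least one non-empty region")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    w_all = regions.weights

    ids = sorted(k for k, v in region_values.items() if len(v[0]) > 0)
    w = w_all.reindex(ids).to_numpy(dtype=float)
    w = w / w.sum()

    m1_draws = np.zeros(cfg.B)
    m2_draws = np.zeros(cfg.B)
    for wc, rid in zip(w, ids):
        L, U = (np.asarray(a, dtype=float) for a in region_values[rid])
        n_c = len(L)
        idx = rng.integers(0, n_c, size=(cfg.B, n_c))
        m1_draws += wc * L[idx].mean(axis=1)
        if cfg.joint_resampling:
            m2_draws += wc * U[idx].mean(axis=1)
        else:
            idx2 = rng.integers(0, n_c, size=(cfg.B, n_c))
            m2_draws += wc * U[idx2].mean(axis=1)

    qlo, qhi = cfg.alpha / 200.0, 1.0 - cfg.alpha / 200.0
    return {
        "m1_low": float(np.quantile(m1_draws, qlo)),
        "m1_high": float(np.quantile(m1_draws, qhi)),
        "m2_low": float(np.quantile(m2_draws, qlo)),
        "m2_high": float(np.quantile(m2_draws, qhi)),
    }


def bootstrap_series(
    stats: pd.DataFrame,
    regions: RegionSet,
    q: int = 1,
    cfg: BootstrapConfig | None = None,
    dates: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Per-day bootstrap CIs for the (optionally q-day pooled) series.

    Returns a date-indexed frame with m1_low, m1_high, m2_low, m2_high;
    days whose window holds no device-days are NaN.
    """
    cfg = cfg or BootstrapConfig()
    el = _eligible_assigned(stats)
    if dates is None:
        dates = pd.date_range(el["date"].min(), el["date"].max(), freq="D")
    rng = np.random.default_rng(cfg.seed)

    by_day: dict[pd.Timestamp, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for (rid, d), g in el.groupby(["region_id", "date"]):
        by_day.setdefault(pd.Timestamp(d), {})[rid] = (
            g["L_km"].to_numpy(dtype=float),
            g["U"].to_numpy(dtype=float),
        )

    rows = {}
    for d in dates:
        window = [d - pd.Timedelta(days=s) for s in range(q)]
        if q > 1 and d - pd.Timedelta(days=q - 1) < dates[0]:
            continue
        pool: dict[str, list[np.ndarray]] = {}
        for day in window:
            for rid, (L, U) in by_day.get(day, {}).items():
                pool.setdefault(rid, [[], []])
                pool[rid][0].append(L)
                pool[rid][1].append(U)
        if not pool:
            continue
        merged = {
            rid: (np.concatenate(v[0]), np.concatenate(v[1])) for rid, v in pool.items()
        }
        rows[d] = bootstrap_aggregate_ci(merged, regions, cfg, rng=rng)

    out = pd.DataFrame.from_dict(rows, orient="index").reindex(dates)
    out.index.name = "date"
    return out
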