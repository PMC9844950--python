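"""Country-level mobility metrics from per-device daily statistics.

Two metrics are estimated per country and day:

* **M1** — the daily average travelled distance per device, in km;
* **M2** — the fraction of devices that travelled less than ``z`` km
  (default 0.2 km) in the calendar day, i.e. did not move beyond indoor
  jitter; reported as a percentage at the output layer.

The estimator is deliberately conservative about positional noise: the
geodesic distance between two consecutive fixes only counts when it is at
least ``r`` times the sum of the two fixes' 1-sigma uncertainties
(``r`` = 1 by default), so a stationary device whose fixes scatter within
the uncertainty disks accrues zero distance.

Devices are stratified by first-level administrative division: each
device-day is assigned to the region containing its daily mean
coordinates, regional means are computed, and the country value is the
population-weighted sum of regional means. Weighting corrects for app
penetration that does not mimic the population distribution. Days on which
some regions have no eligible device renormalise the weights over the
covered regions.

Temporal smoothing (q-day moving average) pools the device-days of the
window per region — i.e. divides the pooled sum by the pooled count — so
days with more devices weigh more, and the bootstrap can resample the
same pool.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, shape

from .geodesy import geodesic_distance
from .trajectory_io import Trajectory

logger = logging.getLogger(__name__)

SMOOTHING_WINDOWS = (1, 7, 14, 21, 28)


@dataclass(frozen=True)
class EstimationConfig:
    """Tunable choices of the daily estimator.

    n: minimum number of observations in the calendar day AND minimum
       temporal span in hours between the first and last of them.
    r: uncertainty-gate multiplier; a segment counts only when its length
       is >= r*(u_m + u_{m+1}).
    z: stationarity threshold in km (strict "<").
    q: smoothing window in days (1 = no smoothing).
    """

    n: int = 12
    r: float = 1.0
    z: float = 0.2
    q: int = 1

    def __post_init__(self):
        if self.n < 2 or self.r <= 0 or self.z <= 0 or self.q < 1:
            raise ValueError(f"invalid estimation config: {self}")


@dataclass
class Region:
    region_id: str
    geometry: object  # shapely (Multi)Polygon, WGS84
    population: float

    def __post_init__(self):
        if self.population <= 0:
            raise ValueError(f"region {self.region_id}: population must be > 0")


@dataclass
class RegionSet:
    """A country's first-level administrative divisions with populations."""

    country: str
    regions: list[Region]

    def __post_init__(self):
        self.regions = sorted(self.regions, key=lambda r: r.region_id)

    @property
    def C(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def weights(self) -> pd.Series:
        """Population weights w_c = p_c / sum_c p_c (they sum to 1)."""
        p = pd.Series(
            [r.population for r in self.regions],
            index=self.region_ids,
            dtype=float,
        )
        return p / p.sum()

    @property
    def total_population(self) -> float:
        return float(sum(r.population for r in self.regions))


def load_regions(geojson_path, country: str = "", populations: Mapping[str, float] | None = None) -> RegionSet:
    """Load a RegionSet from a GeoJSON FeatureCollection.

    Each feature needs a ``region_id`` property; ``population`` is taken
    from feature properties unless a mapping is given (e.g. from a
    population CSV with columns ``region_id,population``).
    """
    with open(geojson_path) as fh:
        fc = json.load(fh)
    regions = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        rid = str(props["region_id"])
        pop = float(populations[rid]) if populations is not None else float(props["population"])
        regions.append(Region(rid, shape(feat["geometry"]), pop))
    return RegionSet(country=country, regions=regions)


def load_populations(csv_path) -> dict[str, float]:
    df = pd.read_csv(csv_path, dtype={"region_id": str})
    return dict(zip(df["region_id"], df["population"].astype(float)))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def gate_distance(l: float, u_m: float, u_m1: float, r: float = 1.0) -> float:
    """Uncertainty gate: keep a segment only if its length is at least
    r*(u_m + u_m1); the boundary is inclusive."""
    return l if l >= r * (u_m + u_m1) else 0.0


def stationarity_flag(L_hat: float, z: float = 0.2) -> int:
    """1 if the daily distance (km) is strictly below the threshold z."""
    return 1 if L_hat < z else 0


def _day_mask(t: np.ndarray, day) -> np.ndarray:
    d0 = np.datetime64(pd.Timestamp(day).normalize(), "s")
    return (t >= d0) & (t < d0 + np.timedelta64(1, "D"))


def eligible(trajectory: Trajectory, day, n: int = 12) -> bool:
    """A device contributes to day d only with >= n observations that day
    spanning >= n hours between the first and the last."""
    m = _day_mask(trajectory.t, day)
    if int(m.sum()) < n:
        return False
    td = trajectory.t[m]
    span = (td.max() - td.min()) / np.timedelta64(1, "h")
    return bool(span >= n)


def daily_distance(trajectory: Trajectory, day, cfg: EstimationConfig | None = None) -> float:
    """Daily travelled distance (km): sum of gated consecutive-pair
    geodesic distances whose earlier endpoint falls in the day.

    The pair bridging the day's last observation to the next day's first
    is attributed to this day only, so travel across midnight is never
    double-counted.
    """
    cfg = cfg or EstimationConfig()
    if len(trajectory) < 2:
        return 0.0
    lat, lon, u, t = trajectory.lat, trajectory.lon, trajectory.u, trajectory.t
    first_in_day = _day_mask(t[:-1], day)
    if not first_in_day.any():
        return 0.0
    idx = np.flatnonzero(first_in_day)
    l = geodesic_distance(lat[idx], lon[idx], lat[idx + 1], lon[idx + 1])
    gated = np.where(l >= cfg.r * (u[idx] + u[idx + 1]), l, 0.0)
    return float(gated.sum()) / 1000.0


def _mean_coords(lat: np.ndarray, lon: np.ndarray) -> tuple[float, float]:
    """Daily mean coordinates; longitudes straddling the antimeridian use
    the circular mean (no study country does, but a wrap must not silently
    put the mean on the wrong side of the planet)."""
    mlat = float(lat.mean())
    if lon.max() - lon.min() > 180.0:
        rad = np.radians(lon)
        mlon = float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
    else:
        mlon = float(lon.mean())
    return mlat, mlon


def assign_region(mean_lat: float, mean_lon: float, regions: RegionSet) -> str | None:
    """Region whose multi-polygon covers the point (boundary inclusive);
    None when no region contains it (e.g. coastal GPS noise)."""
    p = Point(mean_lon, mean_lat)
    for reg in regions.regions:
        if reg.geometry.covers(p):
            return reg.region_id
    return None


def assign_regions(mean_lats: np.ndarray, mean_lons: np.ndarray, regions: RegionSet) -> np.ndarray:
    """Vectorised region assignment; returns object array with None for
    points outside every region."""
    pts = shapely.points(np.asarray(mean_lons, dtype=float), np.asarray(mean_lats, dtype=float))
    out = np.full(len(pts), None, dtype=object)
    unassigned = np.ones(len(pts), dtype=bool)
    for reg in regions.regions:
        if not unassigned.any():
            break
        hit = shapely.covers(reg.geometry, pts) & unassigned
        out[hit] = reg.region_id
        unassigned &= ~hit
    return out


def region_daily_mean(values: Sequence[float]) -> float:
    """Arithmetic mean of eligible devices' values in one region-day."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("region-day with zero devices has no mean")
    return float(arr.mean())


def country_aggregate(region_values: Mapping[str, float], regions: RegionSet) -> float:
    """Population-weighted aggregate over regions; weights renormalised
    over the regions that have a value that day."""
    w = regions.weights
    vals = pd.Series(region_values, dtype=float).reindex(w.index)
    covered = vals.notna()
    if not covered.any():
        raise ValueError("no region has a value; day is missing")
    wc = w[covered]
    return float((vals[covered] * wc / wc.sum()).sum())


# ---------------------------------------------------------------------------
# pipeline: per-device daily statistics and aggregation
# ---------------------------------------------------------------------------


def compute_daily_stats(
    trajectories: Iterable[Trajectory],
    cfg: EstimationConfig | None = None,
    regions: RegionSet | None = None,
) -> pd.DataFrame:
    """Per-device per-day statistics table.

    Columns: trajectory_id, date, n_obs, span_hours, L_km, U, mean_lat,
    mean_lon, eligible (+ region_id when a RegionSet is given). One row
    per device-day with at least one observation. L_km already includes
    the midnight-bridging segment of the day.
    """
    cfg = cfg or EstimationConfig()
    rows = []
    for tr in trajectories:
        if len(tr) == 0:
            continue
        t = tr.t.astype("datetime64[s]")
        days = t.astype("datetime64[D]")
        uniq, inv = np.unique(days, return_inverse=True)
        counts = np.bincount(inv)
        # span within each day
        tsec = t.astype("int64")
        first = np.full(len(uniq), np.iinfo(np.int64).max, dtype=np.int64)
        last = np.full(len(uniq), np.iinfo(np.int64).min, dtype=np.int64)
        np.minimum.at(first, inv, tsec)
        np.maximum.at(last, inv, tsec)
        span_h = (last - first) / 3600.0
        # gated pair distances, attributed to the earlier endpoint's day
        L = np.zeros(len(uniq))
        if len(tr) >= 2:
            l = geodesic_distance(tr.lat[:-1], tr.lon[:-1], tr.lat[1:], tr.lon[1:])
            gated = np.where(l >= cfg.r * (tr.u[:-1] + tr.u[1:]), l, 0.0)
            np.add.at(L, inv[:-1], gated)
        L /= 1000.0
        for j, d in enumerate(uniq):
            sel = inv == j
            mlat, mlon = _mean_coords(tr.lat[sel], tr.lon[sel])
            rows.append(
                (
                    tr.trajectory_id,
                    pd.Timestamp(d),
                    int(counts[j]),
                    float(span_h[j]),
                    float(L[j]),
                    int(L[j] < cfg.z),
                    mlat,
                    mlon,
                    bool(counts[j] >= cfg.n and span_h[j] >= cfg.n),
                )
            )
    stats = pd.DataFrame(
        rows,
        columns=[
            "trajectory_id",
            "date",
            "n_obs",
            "span_hours",
            "L_km",
            "U",
            "mean_lat",
            "mean_lon",
            "eligible",
        ],
    )
    if regions is not None and len(stats):
        stats["region_id"] = assign_regions(
            stats["mean_lat"].to_numpy(), stats["mean_lon"].to_numpy(), regions
        )
        n_out = int(stats["region_id"].isna().sum())
        if n_out:
            logger.info("%d device-days fall outside every region polygon", n_out)
    return stats


def restate_stationarity(stats: pd.DataFrame, z: float) -> pd.DataFrame:
    """Re-derive the stationarity flag from L_km under a new threshold z."""
    out = stats.copy()
    out["U"] = (out["L_km"] < z).astype(int)
    return out


def _eligible_assigned(stats: pd.DataFrame) -> pd.DataFrame:
    if "region_id" not in stats.columns:
        raise ValueError("stats must carry region_id; pass regions to compute_daily_stats")
    return stats[stats["eligible"] & stats["region_id"].notna()]


def aggregate(
    stats: pd.DataFrame,
    regions: RegionSet,
    q: int = 1,
    dates: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Country-level daily M1/M2 series from the device-day table.

    For q > 1 the regional value on day d is the pooled mean over the
    window [d-q+1, d] (pooled sum / pooled device count), then the
    population-weighted country aggregate; the first q-1 days are missing.
    Returns a date-indexed frame with columns m1_km, m2_frac, n (number of
    contributing device-days on the day itself).

    Days with no covered region are absent from the index (or NaN when an
    explicit ``dates`` index is supplied).
    """
    el = _eligible_assigned(stats)
    if el.empty:
        raise ValueError("no eligible device-days assigned to a region")
    if dates is None:
        dates = pd.date_range(el["date"].min(), el["date"].max(), freq="D")

    g = (
        el.groupby(["region_id", "date"])
        .agg(sum_L=("L_km", "sum"), sum_U=("U", "sum"), n=("L_km", "size"))
        .reset_index()
    )
    sum_L = g.pivot(index="date", columns="region_id", values="sum_L").reindex(dates).fillna(0.0)
    sum_U = g.pivot(index="date", columns="region_id", values="sum_U").reindex(dates).fillna(0.0)
    n = g.pivot(index="date", columns="region_id", values="n").reindex(dates).fillna(0.0)

    if q > 1:
        sum_L = sum_L.rolling(q, min_periods=q).sum()
        sum_U = sum_U.rolling(q, min_periods=q).sum()
        n_pool = n.rolling(q, min_periods=q).sum()
    else:
        n_pool = n

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_L = sum_L.where(n_pool > 0) / n_pool.where(n_pool > 0)
        mean_U = sum_U.where(n_pool > 0) / n_pool.where(n_pool > 0)

    w = regions.weights.reindex(mean_L.columns).fillna(0.0)
    wsum = mean_L.notna().mul(w, axis=1).sum(axis=1)
    m1 = mean_L.mul(w, axis=1).sum(axis=1, min_count=1) / wsum.replace(0.0, np.nan)
    m2 = mean_U.mul(w, axis=1).sum(axis=1, min_count=1) / wsum.replace(0.0, np.nan)

    out = pd.DataFrame(
        {
            "m1_km": m1,
            "m2_frac": m2,
            "n": n.sum(axis=1).astype(int),
        },
        index=dates,
    )
    out.index.name = "date"
    return out


def smooth(stats: pd.DataFrame, regions: RegionSet, q: int, dates=None) -> pd.DataFrame:
    """q-day pooled moving average of the country series (q=1 is the
    unsmoothed daily series)."""
    return aggregate(stats, regions, q=q, dates=dates)


def metric_series_frame(
    agg: pd.DataFrame,
    country: str,
    q: int,
    ci: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy output table: one row per (date, metric), M2 as a percentage.

    Columns: country,date,metric,q,estimate,ci_low,ci_high,n_trajectories.
    """
    rows = []
    for metric, col, scale in (("M1", "m1_km", 1.0), ("M2", "m2_frac", 100.0)):
        sub = pd.DataFrame(
            {
                "country": country,
                "date": agg.index,
                "metric": metric,
                "q": q,
                "estimate": agg[col].to_numpy() * scale,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "n_trajectories": agg["n"].to_numpy(),
            }
        )
        if ci is not None:
            lo = ci[f"{metric.lower()}_low"].reindex(agg.index).to_numpy() * scale
            hi = ci[f"{metric.lower()}_high"].reindex(agg.index).to_numpy() * scale
            sub["ci_low"] = lo
            sub["ci_high"] = hi
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)
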