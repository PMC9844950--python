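"""Synthetic trajectory, region, population and mobility-index generation.

Everything downstream of raw data collection can be exercised against
known ground truth: rectangular first-level divisions with populations,
device location streams in the trajectory CSV dialect, and external
mobility-index series in the Community-Mobility-Reports CSV dialect.

Movement model
--------------
Each user has a fixed home inside one region. A day is, independently:

* *missing* (probability ``p_missing_day``) — the device reports nothing;
* a *stay* day (probability ``p_stay``) — the user remains at home, true
  travelled distance 0;
* a *move* day — a round trip home -> destination -> home whose total
  length is log-normal (``trip_meanlog``/``trip_sdlog``, km). The user
  teleports between stay points at the departure and return instants, so
  the true daily distance equals the summed chord lengths and is exactly
  recoverable by a distance estimator from arbitrarily timed fixes.

A per-day mobility multiplier (e.g. :func:`covid_like_profile`) scales the
trip length and the probability of moving, producing the long-term trend
plus weekly cycle that country-level metrics exhibit.

Positional error emulates Wi-Fi/cell positioning: every *place* a user
visits reports fixes with a persistent offset (drawn once per place with
the reported 1-sigma ``noise_u_m``) plus small independent jitter. The
marginal scatter of a fix has standard deviation ``noise_u_m``, but
consecutive fixes from the same place are strongly correlated — which is
what makes the uncertainty gate effective, exactly as for real devices
parked under one Wi-Fi access point. Independent fix-to-fix scatter at the
full reported sigma would defeat any gate at r=1 by construction.

Observation times honour the 20-minute minimum spacing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics_core import Region, RegionSet
from .trajectory_io import Trajectory

M_PER_DEG_LAT = 111_319.5  # good to <0.6% over the globe; fixture scale only


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular synthetic first-level division (<= 2 deg per side)."""

    region_id: str
    lon0: float
    lat0: float
    width: float = 1.0
    height: float = 1.0
    population: float = 1_000_000.0
    n_users: int = 100
    movement: "MovementModel | None" = None  # per-region override

    def __post_init__(self):
        if self.width > 2.0 or self.height > 2.0:
            raise ValueError("synthetic regions are kept <= 2 degrees per side")


@dataclass(frozen=True)
class MovementModel:
    p_stay: float = 0.3
    trip_meanlog: float = math.log(8.0)  # median total round trip, km
    trip_sdlog: float = 0.6
    short_trip_prob: float = 0.15  # errand-only days: a few hundred metres
    short_meanlog: float = math.log(0.25)
    short_sdlog: float = 0.8
    obs_per_day: int = 32
    noise_u_m: float = 25.0
    jitter_frac: float = 0.2  # fraction of sigma that is fix-to-fix jitter
    p_missing_day: float = 0.1
    depart_window_h: tuple[float, float] = (7.0, 11.0)
    return_window_h: tuple[float, float] = (14.0, 21.0)

    def __post_init__(self):
        if not (0 <= self.p_stay <= 1 and 0 <= self.p_missing_day <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.obs_per_day > 72:
            raise ValueError("more than 72 obs/day cannot honour 20-min spacing")
        if self.obs_per_day < 2:
            raise ValueError("need at least 2 obs/day")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    start: str = "2020-03-11"
    n_days: int = 60
    regions: tuple[RegionSpec, ...] = (
        RegionSpec("R01", 8.0, 44.0, 1.5, 1.5, 4_000_000, 120),
        RegionSpec("R02", 10.0, 44.0, 1.5, 1.5, 2_000_000, 60),
        RegionSpec("R03", 8.0, 42.0, 1.5, 1.5, 1_000_000, 40),
    )
    movement: MovementModel = MovementModel()
    mobility: np.ndarray | None = None  # per-day multiplier, len n_days
    country: str = "SYN"

    def profile(self) -> np.ndarray:
        if self.mobility is not None:
            m = np.asarray(self.mobility, dtype=float)
            if len(m) != self.n_days:
                raise ValueError("mobility profile length must equal n_days")
            return m
        return covid_like_profile(self.n_days)


def covid_like_profile(
    n_days: int,
    dip: float = 0.6,
    dip_day: int = 20,
    recovery_days: int = 60,
    weekend_factor: float = 0.75,
    start: str = "2020-03-11",
) -> np.ndarray:
    """Mobility multiplier with a lockdown-like dip plus a weekly cycle."""
    d = np.arange(n_days)
    trend = 1.0 - dip * np.exp(-0.5 * ((d - dip_day) / recovery_days) ** 2) * (
        1 / (1 + np.exp(-(d - dip_day / 4)))
    )
    dow = (pd.Timestamp(start).dayofweek + d) % 7
    weekly = np.where(dow >= 5, weekend_factor, 1.0)
    return trend * weekly


@dataclass
class SimulationResult:
    trajectories: list[Trajectory]
    truth: pd.DataFrame  # user, date, region_id, true_L_km, true_U
    true_series: pd.DataFrame  # date-indexed: m1_km, m2_frac
    region_set: RegionSet


def build_region_set(cfg: SimulationConfig) -> RegionSet:
    from shapely.geometry import box

    regions = [
        Region(r.region_id, box(r.lon0, r.lat0, r.lon0 + r.width, r.lat0 + r.height), r.population)
        for r in cfg.regions
    ]
    return RegionSet(country=cfg.country, regions=regions)


def regions_geojson(cfg: SimulationConfig) -> dict:
    feats = []
    for r in cfg.regions:
        ring = [
            [r.lon0, r.lat0],
            [r.lon0 + r.width, r.lat0],
            [r.lon0 + r.width, r.lat0 + r.height],
            [r.lon0, r.lat0 + r.height],
            [r.lon0, r.lat0],
        ]
        feats.append(
            {
                "type": "Feature",
                "properties": {"region_id": r.region_id, "population": r.population},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def _day_probabilities(model: MovementModel, mobility: np.ndarray):
    """Per-day (p_move, meanlog): the multiplier scales the odds of moving
    and shifts the log trip length."""
    base_move = 1.0 - model.p_stay
    odds = base_move / (1.0 - base_move + 1e-12) * mobility
    p_move = np.clip(odds / (1.0 + odds), 0.0, 1.0)
    meanlog = model.trip_meanlog + np.log(np.maximum(mobility, 1e-9))
    return p_move, meanlog


def _draw_trip_km(
    model: MovementModel, meanlog_day, rng: np.random.Generator, shape
) -> np.ndarray:
    """Round-trip length (km) for move days: a mixture of ordinary trips
    (log-normal, scaled by the day's mobility) and short errand-only trips
    (fixed distribution; lockdowns barely change a walk to the corner shop)."""
    short = rng.random(shape) < model.short_trip_prob
    long_km = np.exp(np.broadcast_to(meanlog_day, shape) + model.trip_sdlog * rng.standard_normal(shape))
    short_km = np.exp(model.short_meanlog + model.short_sdlog * rng.standard_normal(shape))
    return np.where(short, short_km, long_km)


def true_expected_metrics(
    model: MovementModel, mobility: np.ndarray, z: float = 0.2
) -> pd.DataFrame:
    """Analytic per-day expectations of a single user's daily distance and
    stationarity flag under the movement model (used as the estimand in
    coverage experiments)."""
    from scipy.stats import norm

    p_move, meanlog = _day_probabilities(model, mobility)
    ps = model.short_trip_prob
    e_trip = (1 - ps) * np.exp(meanlog + model.trip_sdlog**2 / 2) + ps * math.exp(
        model.short_meanlog + model.short_sdlog**2 / 2
    )
    p_below_z = (1 - ps) * norm.cdf((np.log(z) - meanlog) / model.trip_sdlog) + ps * norm.cdf(
        (math.log(z) - model.short_meanlog) / model.short_sdlog
    )
    return pd.DataFrame(
        {
            "m1_km": p_move * e_trip,
            "m2_frac": (1 - p_move) + p_move * p_below_z,
        }
    )


def simulate_device_days(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_users_override: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Draw per-device daily values directly from the movement model.

    Fast path for experiments that stress the aggregation and bootstrap
    machinery rather than the distance estimator: returns a device-day
    table compatible with :func:`mobimetrics.metrics_core.aggregate`
    (columns trajectory_id, date, region_id, L_km, U, eligible=True).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mobility = cfg.profile()
    dates = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")

    frames = []
    for spec in sorted(cfg.regions, key=lambda r: r.region_id):
        model = spec.movement or cfg.movement
        p_move, meanlog = _day_probabilities(model, mobility)
        n_u = (n_users_override or {}).get(spec.region_id, spec.n_users)
        if n_u == 0:
            continue
        move = rng.random((n_u, cfg.n_days)) < p_move[None, :]
        trip = _draw_trip_km(model, meanlog[None, :], rng, (n_u, cfg.n_days))
        L = np.where(move, trip, 0.0)
        present = rng.random((n_u, cfg.n_days)) >= model.p_missing_day
        uu, dd = np.nonzero(present)
        frames.append(
            pd.DataFrame(
                {
                    "trajectory_id": [f"{spec.region_id}-u{i:05d}" for i in uu],
                    "date": dates[dd],
                    "region_id": spec.region_id,
                    "L_km": L[uu, dd],
                    "U": (L[uu, dd] < 0.2).astype(int),
                    "eligible": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _obs_times_minutes(n_obs: int, rng: np.random.Generator) -> np.ndarray:
    """Observation offsets within the day (minutes), >= 20 min apart."""
    interval = 24 * 60 / n_obs
    base = np.arange(n_obs) * interval
    amp = max((interval - 20.0) / 2.0, 0.0)
    return base + rng.uniform(-amp, amp, size=n_obs)


def simulate_trajectories(cfg: SimulationConfig) -> SimulationResult:
    """Generate full observation streams plus ground truth.

    Reproducible given ``cfg.seed``; the same config yields byte-identical
    trajectory CSVs via :func:`mobimetrics.trajectory_io.write_trajectories`.
    """
    rng = np.random.default_rng(cfg.seed)
    mobility = cfg.profile()
    dates = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")
    day_starts = dates.to_numpy(dtype="datetime64[s]").astype("int64")

    trajectories: list[Trajectory] = []
    truth_rows = []

    for spec in sorted(cfg.regions, key=lambda r: r.region_id):
        model = spec.movement or cfg.movement
        p_move, meanlog = _day_probabilities(model, mobility)
        sigma = model.noise_u_m
        jit = model.jitter_frac * sigma
        offs = sigma * math.sqrt(max(1.0 - model.jitter_frac**2, 0.0))
        for ui in range(spec.n_users):
            uid = f"{spec.region_id}-u{ui:05d}"
            home_lon = spec.lon0 + rng.uniform(0.05, 0.95) * spec.width
            home_lat = spec.lat0 + rng.uniform(0.05, 0.95) * spec.height
            m_per_deg_lon = M_PER_DEG_LAT * math.cos(math.radians(home_lat))
            home_off = offs * rng.standard_normal(2)  # persistent home-fix offset, m

            move = rng.random(cfg.n_days) < p_move
            present = rng.random(cfg.n_days) >= model.p_missing_day
            trip_km = _draw_trip_km(model, meanlog, rng, (cfg.n_days,))

            ts_all, lat_all, lon_all = [], [], []
            for d in range(cfg.n_days):
                true_L = 0.0
                if move[d]:
                    half_m = trip_km[d] * 1000.0 / 2.0
                    bearing = rng.uniform(0, 2 * math.pi)
                    dest_lat = home_lat + half_m * math.cos(bearing) / M_PER_DEG_LAT
                    dest_lon = home_lon + half_m * math.sin(bearing) / m_per_deg_lon
                    true_L = trip_km[d]
                truth_rows.append(
                    (uid, dates[d], spec.region_id, true_L, int(true_L < 0.2))
                )
                if not present[d]:
                    continue
                mins = _obs_times_minutes(model.obs_per_day, rng)
                hours = mins / 60.0
                if move[d]:
                    t1 = rng.uniform(*model.depart_window_h)
                    t2 = rng.uniform(*model.return_window_h)
                    away = (hours >= t1) & (hours < t2)
                    dest_off = offs * rng.standard_normal(2)
                else:
                    away = np.zeros(model.obs_per_day, dtype=bool)
                    dest_off = home_off
                base_lat = np.where(away, dest_lat if move[d] else home_lat, home_lat)
                base_lon = np.where(away, dest_lon if move[d] else home_lon, home_lon)
                off_n = np.where(away, dest_off[0], home_off[0])
                off_e = np.where(away, dest_off[1], home_off[1])
                err_n = off_n + jit * rng.standard_normal(model.obs_per_day)
                err_e = off_e + jit * rng.standard_normal(model.obs_per_day)
                lat_all.append(base_lat + err_n / M_PER_DEG_LAT)
                lon_all.append(base_lon + err_e / m_per_deg_lon)
                ts_all.append(day_starts[d] + np.round(mins * 60).astype("int64"))
            if not ts_all:
                continue
            t = np.concatenate(ts_all).astype("datetime64[s]")
            trajectories.append(
                Trajectory(
                    trajectory_id=uid,
                    lat=np.concatenate(lat_all),
                    lon=np.concatenate(lon_all),
                    u=np.full(t.shape, sigma),
                    t=t,
                    country=cfg.country,
                )
            )

    truth = pd.DataFrame(
        truth_rows, columns=["user", "date", "region_id", "true_L_km", "true_U"]
    )
    region_set = build_region_set(cfg)
    true_series = true_country_series(truth, region_set)
    return SimulationResult(trajectories, truth, true_series, region_set)


def true_country_series(truth: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Population-weighted ground-truth country series over ALL users
    (whether or not their device reported that day)."""
    g = (
        truth.groupby(["date", "region_id"])[["true_L_km", "true_U"]]
        .mean()
        .reset_index()
    )
    w = regions.weights
    g["w"] = g["region_id"].map(w)
    agg = g.groupby("date").apply(
        lambda x: pd.Series(
            {
                "m1_km": (x["true_L_km"] * x["w"]).sum() / x["w"].sum(),
                "m2_frac": (x["true_U"] * x["w"]).sum() / x["w"].sum(),
            }
        ),
        include_groups=False,
    )
    agg.index = pd.DatetimeIndex(agg.index)
    agg.index.name = "date"
    return agg


# ---------------------------------------------------------------------------
# synthetic external mobility indices
# ---------------------------------------------------------------------------


def simulate_index(
    true_series: pd.Series,
    noise_sd: float = 5.0,
    scale: float = 1.0,
    baseline_days: int = 14,
    seed: int = 0,
) -> pd.Series:
    """Percent-change-from-baseline index derived from a true series.

    index = 100 * (scale*x - baseline_mean) / baseline_mean + noise, with
    the baseline the mean of the first ``baseline_days`` (of scale*x).
    ``scale=-1`` yields a workplaces-like, negatively-correlated index.
    """
    x = true_series.astype(float) * scale
    base = x.iloc[:baseline_days].mean()
    if base == 0:
        raise ValueError("baseline mean is zero; cannot form a percent change")
    rng = np.random.default_rng(seed)
    idx = 100.0 * (x - base) / abs(base) + noise_sd * rng.standard_normal(len(x))
    idx.name = true_series.name
    return idx


CMR_INDEX_COLUMNS = [
    "retail_and_recreation_percent_change_from_baseline",
    "grocery_and_pharmacy_percent_change_from_baseline",
    "parks_percent_change_from_baseline",
    "transit_stations_percent_change_from_baseline",
    "workplaces_percent_change_from_baseline",
    "residential_percent_change_from_baseline",
]


def write_cmr_csv(indices: dict[str, dict[str, pd.Series]], path) -> None:
    """Write country-level index series in the Community Mobility Reports
    CSV dialect (one row per country-date, empty sub_region_1)."""
    rows = []
    for country, series_map in indices.items():
        all_dates = sorted(set().union(*(set(s.index) for s in series_map.values())))
        for d in all_dates:
            row = {
                "country_region_code": country,
                "country_region": country,
                "sub_region_1": "",
                "sub_region_2": "",
                "metro_area": "",
                "iso_3166_2_code": "",
                "census_fips_code": "",
                "place_id": "",
                "date": pd.Timestamp(d).strftime("%Y-%m-%d"),
            }
            for col in CMR_INDEX_COLUMNS:
                name = col.replace("_percent_change_from_baseline", "")
                s = series_map.get(name)
                row[col] = round(float(s.loc[d]), 3) if s is not None and d in s.index else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
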