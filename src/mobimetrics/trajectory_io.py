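"""Reading, validation and sanitation of smartphone trajectory streams.

A raw observation is the tuple ``(id, lat, lon, u, timestamp)``: an opaque
anonymised device identifier, WGS84 coordinates in degrees, a 1-sigma
positional uncertainty in metres, and a local wall-clock timestamp.
Consecutive observations of one trajectory are at least 20 minutes apart;
rows violating the spacing (including duplicate timestamps) are thinned —
the earlier row is kept — and counted, because the spacing is a property
the delivered stream is supposed to have, not a reason to reject a device.

Sanitation follows two fixed rules:

* rows with latitude AND longitude exactly zero are dropped (the value a
  smartphone reports when geolocation failed);
* non-positive uncertainties are replaced with 25 m, the typical accuracy
  of Wi-Fi / cell-tower positioning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SPACING = pd.Timedelta(minutes=20)
DEFAULT_UNCERTAINTY_M = 25.0

COLUMNS = ["id", "lat", "lon", "u", "timestamp"]


@dataclass(frozen=True)
class Observation:
    """A single location fix of one device."""

    trajectory_id: str
    lat: float
    lon: float
    u: float  # metres, 1-sigma
    t: pd.Timestamp  # local wall-clock time


@dataclass
class Trajectory:
    """Time-ordered location fixes of one anonymised device.

    Fields are parallel numpy arrays for vectorised processing; the
    ``observations`` iterator yields :class:`Observation` records.
    """

    trajectory_id: str
    lat: np.ndarray
    lon: np.ndarray
    u: np.ndarray
    t: np.ndarray  # datetime64[s]
    country: str = ""

    def __len__(self) -> int:
        return len(self.lat)

    @property
    def observations(self) -> Iterator[Observation]:
        for i in range(len(self)):
            yield Observation(
                self.trajectory_id,
                float(self.lat[i]),
                float(self.lon[i]),
                float(self.u[i]),
                pd.Timestamp(self.t[i]),
            )


@dataclass
class SanitationReport:
    n_removed_zero_coord: int = 0
    n_replaced_uncertainty: int = 0
    n_total_observations: int = 0
    n_dropped_empty_trajectories: int = 0

    @property
    def fraction_replaced(self) -> float:
        if self.n_total_observations == 0:
            return 0.0
        return self.n_replaced_uncertainty / self.n_total_observations

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_removed_zero_coord": self.n_removed_zero_coord,
                "n_replaced_uncertainty": self.n_replaced_uncertainty,
                "n_total_observations": self.n_total_observations,
                "n_dropped_empty_trajectories": self.n_dropped_empty_trajectories,
                "fraction_replaced": self.fraction_replaced,
            }
        )


def _thin_spacing(t: np.ndarray) -> np.ndarray:
    """Boolean keep-mask enforcing >= 20 min between consecutive kept rows.

    Greedy from the earliest row: a row is kept iff it is at least 20
    minutes after the last kept row, so the earlier of a violating pair
    survives (duplicate timestamps are thinned the same way).
    """
    keep = np.zeros(len(t), dtype=bool)
    if len(t) == 0:
        return keep
    keep[0] = True
    last = t[0]
    step = np.timedelta64(20, "m")
    for i in range(1, len(t)):
        if t[i] - last >= step:
            keep[i] = True
            last = t[i]
    return keep


def frame_to_trajectories(df: pd.DataFrame, country: str = "") -> list[Trajectory]:
    """Group a raw observation table into spacing-valid trajectories."""
    n_thinned = 0
    out: list[Trajectory] = []
    for tid, g in df.groupby("id", sort=True):
        g = g.sort_values("timestamp", kind="stable")
        t = g["timestamp"].to_numpy(dtype="datetime64[s]")
        keep = _thin_spacing(t)
        n_thinned += int((~keep).sum())
        out.append(
            Trajectory(
                trajectory_id=str(tid),
                lat=g["lat"].to_numpy(dtype=float)[keep],
                lon=g["lon"].to_numpy(dtype=float)[keep],
                u=g["u"].to_numpy(dtype=float)[keep],
                t=t[keep],
                country=country,
            )
        )
    if n_thinned:
        logger.info("thinned %d observations violating the 20-min spacing", n_thinned)
    return out


def read_trajectories(path, country: str = "") -> list[Trajectory]:
    """Read a trajectory CSV (columns ``id,lat,lon,u,timestamp``).

    Rows that fail to parse are skipped with a logged count; an empty file
    yields an empty list with a warning. Timestamps are local wall-clock
    ISO-8601 without zone offset.
    """
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        logger.warning("empty trajectory file: %s", path)
        return []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} lacks columns {missing}")
    if df.empty:
        logger.warning("trajectory file has no rows: %s", path)
        return []

    n0 = len(df)
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["u"] = pd.to_numeric(df["u"], errors="coerce")
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = df[["id", "lat", "lon", "u", "timestamp"]].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: skipped %d unparsable rows", path, int(bad.sum()))
        df = df[~bad]
    logger.info("%s: %d rows read, %d kept", path, n0, len(df))
    return frame_to_trajectories(df, country=country)


def trajectories_to_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    parts = []
    for tr in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    "id": tr.trajectory_id,
                    "lat": tr.lat,
                    "lon": tr.lon,
                    "u": tr.u,
                    "timestamp": pd.DatetimeIndex(tr.t),
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=COLUMNS)
    return pd.concat(parts, ignore_index=True)


def write_trajectories(trajectories: Iterable[Trajectory], path) -> None:
    df = trajectories_to_frame(trajectories)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def sanitize(
    trajectories: Iterable[Trajectory],
) -> tuple[list[Trajectory], SanitationReport]:
    """Apply the fixed sanitation rules; never touches valid rows.

    Idempotent: a second pass reports zero removals and replacements.
    Trajectories left without observations are dropped.
    """
    report = SanitationReport()
    out: list[Trajectory] = []
    for tr in trajectories:
        report.n_total_observations += len(tr)
        keep = ~((tr.lat == 0.0) & (tr.lon == 0.0))
        report.n_removed_zero_coord += int((~keep).sum())
        u = tr.u[keep]
        bad_u = u <= 0.0
        report.n_replaced_uncertainty += int(bad_u.sum())
        u = np.where(bad_u, DEFAULT_UNCERTAINTY_M, u)
        if not keep.any():
            report.n_dropped_empty_trajectories += 1
            continue
        out.append(
            Trajectory(
                trajectory_id=tr.trajectory_id,
                lat=tr.lat[keep],
                lon=tr.lon[keep],
                u=u,
                t=tr.t[keep],
                country=tr.country,
            )
        )
    logger.info(
        "sanitize: removed %d zero-coordinate rows, replaced %d uncertainties (%.4f%%)",
        report.n_removed_zero_coord,
        report.n_replaced_uncertainty,
        100 * report.fraction_replaced,
    )
    return out, report
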