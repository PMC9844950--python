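import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from mobimetrics import (
    Region,
    RegionSet,
    RegionSpec,
    SimulationConfig,
    Trajectory,
)
from mobimetrics import synthetic


def make_trajectory(tid, points, u=25.0, country="SYN"):
    """Build a Trajectory from (timestamp-string, lat, lon[, u]) tuples."""
    ts, lats, lons, us = [], [], [], []
    for p in points:
        ts.append(np.datetime64(p[0], "s"))
        lats.append(p[1])
        lons.append(p[2])
        us.append(p[3] if len(p) > 3 else u)
    return Trajectory(
        trajectory_id=tid,
        lat=np.array(lats, float),
        lon=np.array(lons, float),
        u=np.array(us, float),
        t=np.array(ts),
        country=country,
    )


@pytest.fixture
def two_region_set():
    """Two disjoint rectangles with a 75/25 population split."""
    return RegionSet(
        country="SYN",
        regions=[
            Region("A", box(8.0, 44.0, 9.5, 45.5), 75.0),
            Region("B", box(10.0, 44.0, 11.5, 45.5), 25.0),
        ],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A moderate full-trajectory simulation shared across tests."""
    cfg = SimulationConfig(
        seed=42,
        n_days=40,
        regions=(
            RegionSpec("A", 8.0, 44.0, 1.5, 1.5, 3_000_000, 40),
            RegionSpec("B", 10.0, 44.0, 1.5, 1.5, 1_000_000, 20),
        ),
    )
    return synthetic.simulate_trajectories(cfg)
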