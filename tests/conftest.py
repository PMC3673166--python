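"""Shared fixtures: small synthetic cohorts regenerated per session."""

import numpy as np
import pandas as pd
import pytest

from shearwater.labelling import label_track
from shearwater.model import FeatureWindows, ModelConfig, make_windows
from shearwater.synthetic import (
    SimConfig,
    simulate_annual_cycle,
    simulate_foraging_cohort,
    simulate_foraging_trip,
)


def equator_track(speeds_mps, dt_s=60.0, start_lon=0.0):
    """Track moving east along the equator with prescribed segment speeds."""
    deg_per_m = 1.0 / 111_194.92664455873  # 6371 km sphere
    lons = np.concatenate([[start_lon], start_lon + np.cumsum(np.asarray(speeds_mps) * dt_s) * deg_per_m])
    times = pd.Timestamp("2008-06-01T12:00:00Z") + pd.to_timedelta(
        np.arange(len(lons)) * dt_s, unit="s"
    )
    return pd.DataFrame({"time": times, "lat": 0.0, "lon": lons})


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def trip(sim_config):
    return simulate_foraging_trip(sim_config, seed=42, n_fixes=500)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate_foraging_cohort(sim_config, seed=0)


@pytest.fixture(scope="session")
def cohort_windows(cohort):
    cfg = ModelConfig()
    parts = [make_windows(b.logger, label_track(b.track), cfg) for b in cohort]
    return FeatureWindows(
        X=np.vstack([p.X for p in parts]),
        center_time=pd.DatetimeIndex(np.concatenate([p.center_time for p in parts])),
        labels=np.concatenate([p.labels for p in parts]),
    )


@pytest.fixture(scope="session")
def annual_bird(sim_config):
    return simulate_annual_cycle(sim_config, seed=7)


@pytest.fixture(scope="session")
def annual_daily(annual_bird):
    tr = annual_bird.track.copy()
    tr["date"] = pd.DatetimeIndex(tr["time"]).date
    return tr.groupby("date")[["lat", "lon"]].mean().reset_index()
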