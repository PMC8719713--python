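import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from whimtrack import io as wio
from whimtrack import simulate

UTC = "UTC"


def make_fix(animal="a", t="2020-06-01T00:00:00", lat=60.0, lon=-90.0, lc="LC3"):
    ts = pd.Timestamp(t)
    ts = ts.tz_localize(UTC) if ts.tzinfo is None else ts.tz_convert(UTC)
    return wio.Fix(animal_id=animal, timestamp=ts, lat=lat, lon=lon, location_class=lc)


def make_track(positions, animal="a", start="2020-06-01T00:00:00", step_h=1.0,
               lc="LC3"):
    """Track from a list of (lat, lon) at a regular hourly cadence."""
    t0 = pd.Timestamp(start, tz=UTC)
    fixes = [wio.Fix(animal_id=animal, timestamp=t0 + pd.Timedelta(hours=i * step_h),
                     lat=la, lon=lo, location_class=lc)
             for i, (la, lo) in enumerate(positions)]
    return wio.Track(animal_id=animal, fixes=fixes)


@pytest.fixture(scope="session")
def mackenzie_schedule():
    return simulate.load_preset("mackenzie_delta")


@pytest.fixture(scope="session")
def hudson_schedule():
    return simulate.load_preset("hudson_bay")


@pytest.fixture(scope="session")
def noise_free_move():
    """Always-on transmitter, zero positional error: the exact-recovery limit."""
    return simulate.MovementConfig(
        lc_error_m={k: 0.0 for k in ["LC3", "LC2", "LC1", "LC0", "LCA", "LCB"]},
        duty_cycle=None, sampling_interval_h=1.0)


@pytest.fixture(scope="session")
def duty_cycled_move():
    return simulate.MovementConfig()     # 48 h off / 10 h on, full error model


@pytest.fixture(scope="session")
def small_md_pair(mackenzie_schedule, duty_cycled_move):
    """One duty-cycled Mackenzie Delta animal with its truth log."""
    return simulate.generate_annual_track(mackenzie_schedule, duty_cycled_move, seed=7)
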