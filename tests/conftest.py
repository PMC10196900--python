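import warnings

import numpy as np
import pandas as pd
import pytest

from drinksense.cohort import CohortConfig, simulate_cohort
from drinksense.io import SensorStreams
from drinksense.pipeline import prepare_events

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant, 4-week cohort shared across tests (seed 7)."""
    cfg = CohortConfig(n_participants=12, n_weeks=4, seed=7)
    streams, truth = simulate_cohort(cfg)
    return cfg, streams, truth


@pytest.fixture(scope="session")
def small_events(small_cohort):
    _, streams, _ = small_cohort
    events, log = prepare_events(streams, seed=7)
    return events, log


def gps_frame(pid, t, lat, lon, tz=0):
    """Build a minimal GPS stream (UTC seconds from local inputs)."""
    t = np.asarray(t, dtype=float)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "t": t - tz,
            "lat": np.asarray(lat, dtype=float),
            "lon": np.asarray(lon, dtype=float),
            "accuracy": 10.0,
        }
    )


def one_participant_streams(pid="pX", gps=None, accel=None, comm=None,
                            device=None, wifi=None, sex="female", tz=0):
    parts = pd.DataFrame(
        {
            "participant_id": [pid],
            "sex": [sex],
            "enrolled_days": [28],
            "tz_offset_s": [tz],
        }
    )
    kw = {"participants": parts}
    for name, df in (
        ("gps", gps), ("accel", accel), ("comm", comm),
        ("device", device), ("wifi", wifi),
    ):
        if df is not None:
            kw[name] = df.sort_values("t").reset_index(drop=True)
    return SensorStreams(**kw)
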