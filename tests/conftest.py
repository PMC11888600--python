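import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import thermomaze as tm
from thermomaze.config import QUADRANT_LABELS

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def short_config():
    """A structurally complete but short session: 1 min Pre/Post, 20 min
    Cooling with four 75-s warm-spot epochs per cycle (one cycle)."""
    cfg = tm.SessionConfig(
        sub_sessions=[("Pre", 0.0, 60.0), ("Cooling", 60.0, 1260.0),
                      ("Post", 1260.0, 1320.0)],
        warm_spot_schedule=[], rng_seed=123,
    )
    cfg.warm_spot_schedule = tm.corner_schedule(
        cfg.sub_session("Cooling"), epoch_s=300.0, n_cycles=1)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def short_session(short_config):
    return tm.simulate_session(short_config, n_units=12, with_lfp=False,
                               n_ripples=150)


def make_events(peaks, quadrants, duration=0.08):
    """Event table from peak times and quadrant indices/labels."""
    peaks = np.asarray(peaks, dtype=float)
    quads = [QUADRANT_LABELS[q] if not isinstance(q, str) else q
             for q in np.atleast_1d(quadrants)]
    return pd.DataFrame({
        "start_s": peaks - duration / 2,
        "peak_s": peaks,
        "end_s": peaks + duration / 2,
        "duration_s": duration,
        "quadrant": quads,
    })
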