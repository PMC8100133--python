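import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nocimec import SubjectGroundTruth


@pytest.fixture
def truth() -> SubjectGroundTruth:
    """Default noiseless simulated subject."""
    return SubjectGroundTruth()


def make_trace(beat_times, **columns) -> pd.DataFrame:
    """Hand-built feature trace; unspecified parameters held constant."""
    t = np.asarray(beat_times, dtype=float)
    base = {"K": 1.0, "hr": 60.0, "sbp": 100.0, "ppg_amp": 2.0}
    base.update(columns)
    data = {"beat_time": t}
    for col, val in base.items():
        arr = np.asarray(val, dtype=float)
        data[col] = np.full_like(t, float(arr)) if arr.ndim == 0 else arr
    data["B"] = np.full_like(t, 0.2)
    data["r_squared"] = np.full_like(t, 1.0)
    data["valid"] = np.ones_like(t, dtype=bool)
    return pd.DataFrame(data)


@pytest.fixture
def trace_builder():
    return make_trace
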