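import numpy as np
import pandas as pd
import pytest

from trajspace.core import EpochedRecording, ctf_sensor_names, default_times


def make_meta(n, seen=None, orientation=None, response=None, subject="S01"):
    rng = np.random.default_rng(7)
    if seen is None:
        seen = rng.integers(0, 2, n)
    if orientation is None:
        orientation = np.where(rng.random(n) < 0.5, "left", "right")
    if response is None:
        response = orientation.copy() if hasattr(orientation, "copy") else np.asarray(orientation)
    orientation = np.asarray(orientation)
    response = np.asarray(response)
    return pd.DataFrame({
        "subject_id": subject,
        "session_id": "sess1",
        "seen": np.asarray(seen, int),
        "orientation": orientation,
        "response": response,
        "correct": (response == orientation).astype(int),
    })


def make_recording(n_trials=5, n_sensors=4, fs=100.0, t_start=-0.5, t_stop=0.5,
                   data=None, seed=0, **meta_kw):
    times = default_times(fs, t_start, t_stop)
    if data is None:
        data = np.random.default_rng(seed).standard_normal((n_trials, n_sensors, len(times)))
    return EpochedRecording(
        data=data,
        fs=fs,
        times=times,
        sensor_names=ctf_sensor_names(n_sensors),
        meta=make_meta(n_trials, **meta_kw),
        band="raw",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rec():
    return make_recording()
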