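import numpy as np
import pandas as pd
import pytest

from henrec.signals_io import InertialRecording, LabelInterval
from henrec.windowing import WindowInstance


def make_recording(hen_id="hen01", sf=100.0, n=1000, seed=0):
    """A finite random recording with a regular time base."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "timestamp_s": np.arange(n) / sf,
            "acc_x": rng.normal(0, 2, n),
            "acc_y": rng.normal(0, 2, n),
            "acc_z": rng.normal(9.8, 2, n),
            "gyr_x": rng.normal(0, 30, n),
            "gyr_y": rng.normal(0, 30, n),
            "gyr_z": rng.normal(0, 30, n),
        }
    )
    return InertialRecording(hen_id, sf, data)


def make_window(samples, hen_id="hen01", behavior="ST", start_s=0.0):
    return WindowInstance(hen_id, behavior, start_s, np.asarray(samples, dtype=float))


def random_window(n=64, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return make_window(rng.normal(0, scale, size=(n, 6)))


@pytest.fixture
def rec100():
    return make_recording()


@pytest.fixture
def interval():
    return LabelInterval("hen01", "ET", 0.0, 1.92)
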