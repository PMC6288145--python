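import numpy as np
import pytest

from actigwas.classifier import STATES
from actigwas.preprocess import RawRecording
from actigwas.synthetic import SimProfile, StateSignal, simulate_accelerometer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def diverse_profile():
    """Orientation-diverse, stationary-rich profile for calibration tests."""
    dwell = {"sleep": 15.0, "sedentary": 15.0, "walking": 2.0, "moderate": 2.0}
    return dict(duration_h=4.0, sample_rate=25.0, state_dwell_min=dwell)


@pytest.fixture(scope="session")
def short_recording():
    """A small simulated recording plus truth, reused across read-only tests."""
    dwell = {"sleep": 8.0, "sedentary": 8.0, "walking": 3.0, "moderate": 3.0}
    profile = SimProfile(seed=21, duration_h=1.25, sample_rate=25.0, state_dwell_min=dwell)
    return simulate_accelerometer(profile)


@pytest.fixture
def still_recording():
    """Over an hour of a perfectly still device at a fixed orientation."""
    n = int(3700 * 25)
    t = np.arange(n) / 25.0
    a = np.zeros((n, 3))
    a[:, 2] = 1.0
    return RawRecording(t, a)
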