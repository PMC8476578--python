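import numpy as np
import pytest

import coordkin as ck
from coordkin.io_model import SAMPLE_PERIOD


@pytest.fixture(scope="session")
def small_course():
    return ck.generate_course(10, seed=1)


@pytest.fixture(scope="session")
def straight_course():
    """Ten collinear coins along +x, 58 m apart."""
    coins = np.zeros((10, 3))
    coins[:, 0] = 58.0 * np.arange(10)
    coins[:, 2] = 30.0
    return ck.CoinCourse(coins, tuple(["forward"] * 9))


@pytest.fixture(scope="session")
def clean_flight(small_course):
    cfg = ck.SynthConfig(seed=42, coupling=0.8, overshoot_gain=1.0, noise_sd=0.5)
    return ck.simulate_flight_trial(cfg, small_course)


def make_series(t, pitch=None, roll=None, yaw=None):
    n = len(t)
    zero = np.zeros(n)
    return ck.AngleSeries(
        np.asarray(t, dtype=float),
        zero if pitch is None else np.asarray(pitch, dtype=float),
        zero if roll is None else np.asarray(roll, dtype=float),
        zero if yaw is None else np.asarray(yaw, dtype=float),
    )


@pytest.fixture
def grid():
    return SAMPLE_PERIOD * np.arange(120)
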