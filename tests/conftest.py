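import numpy as np
import pytest

from hpr.basis import CANONICAL_PARAMS, DEFAULT_PARAMS_NAME, gamma_rf
from hpr.beat_detect import BeatTimes


@pytest.fixture
def rng():
    return np.random.default_rng(20160307)


@pytest.fixture(scope="session")
def canonical():
    """Default canonical basis function on the 10 Hz epoch grid."""
    return gamma_rf(CANONICAL_PARAMS[DEFAULT_PARAMS_NAME], fs=10.0, duration=11.0)


@pytest.fixture
def periodic_beats():
    """Strictly periodic 0.8 s beat train over 60 s."""
    return BeatTimes(times=np.arange(0.0, 60.0, 0.8))


def make_beats(ibis, t0=0.0):
    """Beat train from an explicit IBI sequence."""
    times = np.concatenate([[t0], t0 + np.cumsum(ibis)])
    return BeatTimes(times=times)
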