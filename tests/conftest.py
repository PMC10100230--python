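import numpy as np
import pytest

from esis import SurvivalSamples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_survival(rng, n, censor_prob=0.3):
    """Small random right-censored sample with at least one event."""
    y = rng.exponential(10.0, n) + 0.01
    delta = (rng.random(n) > censor_prob).astype(int)
    if delta.sum() == 0:
        delta[int(rng.integers(n))] = 1
    return SurvivalSamples(y, delta)
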