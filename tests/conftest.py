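import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_survival_instance(rng, n, tie_prob=0.3, censor_prob=0.4):
    """Random survival instance with ties and censoring, >= 1 event."""
    if rng.uniform() < tie_prob:
        times = rng.integers(1, max(2, n // 2), size=n).astype(float)
    else:
        times = rng.exponential(10.0, size=n) + 0.1
    events = (rng.uniform(size=n) > censor_prob).astype(int)
    if events.sum() == 0:
        events[rng.integers(0, n)] = 1
    h = rng.normal(size=n)
    if rng.uniform() < 0.3:  # hazard ties
        h = np.round(h, 1)
    return h, times, events
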