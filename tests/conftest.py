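import numpy as np
import pytest

from eaccd.cohort import Observations


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


def make_obs(times, events=None):
    times = np.asarray(times, float)
    if events is None:
        events = np.ones_like(times, dtype=int)
    return Observations(times, np.asarray(events, int))


@pytest.fixture
def obs_factory():
    return make_obs


def random_censored_sample(rng, n, rate=0.01, horizon=156.0, loss=0.2):
    event_times = rng.exponential(1.0 / rate, n)
    censor = np.full(n, horizon)
    lost = rng.random(n) < loss
    censor[lost] = np.minimum(censor[lost], rng.uniform(0, horizon, int(lost.sum())))
    observed = np.minimum(event_times, censor)
    return Observations(observed, (event_times <= censor).astype(int))
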