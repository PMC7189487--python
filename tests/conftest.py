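import numpy as np
import pytest

from owlsync import trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def poisson_trialset(rate, n_trials, duration, rng, unit_id="poisson",
                     analysis_start=0.0):
    """Homogeneous Poisson TrialSet (independent across trials)."""
    spikes = [np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
              for _ in range(n_trials)]
    return trials.TrialSet(unit_id, spikes, duration,
                           analysis_start=analysis_start)


@pytest.fixture
def poisson_ts(rng):
    return poisson_trialset(50.0, 200, 1.0, rng)
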