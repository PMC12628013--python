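import numpy as np
import pytest

from revlearn.trial_data import TrialSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def chance_sequence(rng):
    """100-trial chance-level subject."""
    return TrialSequence(
        subject_id="C01", task="AL",
        outcomes=(rng.random(100) < 0.5).astype(int),
    )


@pytest.fixture
def learner_sequence(rng):
    """Gradual learner: success probability rises logistically over 80 trials."""
    t = np.arange(1, 81)
    p = 1.0 / (1.0 + np.exp(-(-1.0 + 0.08 * t)))
    return TrialSequence(
        subject_id="L01", task="AL",
        outcomes=(rng.random(80) < p).astype(int),
    )
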