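import numpy as np
import pytest

from socialrl.tasks import TrialRecordDG, TrialRecordPRL


def make_prl(choices, rewards):
    """Build contiguous PRL records from parallel choice/reward lists."""
    return [
        TrialRecordPRL(trial=t + 1, choice=c, reward=float(r))
        for t, (c, r) in enumerate(zip(choices, rewards))
    ]


def make_dg(returns, hi, si):
    return [
        TrialRecordDG(trial=t + 1, partner_return=float(r),
                      hi_rating=float(h), si_rating=float(s))
        for t, (r, h, s) in enumerate(zip(returns, hi, si))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_prl_data(rng):
    """60 trials of arbitrary (choice, reward) pairs."""
    choices = rng.integers(1, 4, size=60)
    rewards = np.where(rng.random(60) < 0.5, 10.0, -5.0)
    return make_prl(choices, rewards)


@pytest.fixture
def random_dg_data(rng):
    returns = np.where(rng.random(20) < 0.5, 0.0, 0.5)
    hi = rng.integers(0, 101, size=20)
    si = rng.integers(0, 101, size=20)
    return make_dg(returns, hi, si)
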