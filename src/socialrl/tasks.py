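"""Generative environments for the two behavioural paradigms.

Two tasks are modelled:

* A three-option probabilistic reversal-learning (PRL) task: 60 trials, one
  option rewards +10 points with probability 0.8, one with 0.5, one with 0.2
  (otherwise -5).  After trial 30 the contingencies rotate covertly: the
  lowest-probability option becomes the high one, the highest becomes the
  even one, and the even becomes the low one.

* A repeated-reversal Dictator game: 20 trials in which a partner either
  splits 10 points fairly (return r = 0.5) or keeps everything (r = 0).  The
  partner follows an 80/20 unfair-or-fair policy in the first 10 trials which
  reverses from trial 11.  After each return the participant rates the
  partner's harmful intent and self-interest on 0-100 scales.

Trial indexing is 1-based throughout; "reversal_trial" is the last trial of
the first block, so the reversed contingencies apply from reversal_trial + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

REWARD_WIN = 10.0
REWARD_LOSS = -5.0

#: Contingency rotation at the PRL reversal: low->high, high->even, even->low.
_ROTATION = {0.8: 0.5, 0.5: 0.2, 0.2: 0.8}


@dataclass(frozen=True)
class TrialRecordPRL:
    """One PRL trial: 1-based trial index, chosen option (1-3), points won."""

    trial: int
    choice: int
    reward: float

    def __post_init__(self) -> None:
        if self.choice not in (1, 2, 3):
            raise ValueError(f"choice must be in {{1,2,3}}, got {self.choice}")
        if self.reward not in (REWARD_WIN, REWARD_LOSS):
            raise ValueError(
                f"reward must be {REWARD_WIN:+g} or {REWARD_LOSS:+g}, got {self.reward}"
            )


@dataclass(frozen=True)
class TrialRecordDG:
    """One Dictator-game trial.

    ``partner_return`` is 0.5 for a fair split and 0.0 for keeping the points;
    ``hi_rating`` / ``si_rating`` are the 0-100 harmful-intent and
    self-interest attribution ratings given after observing the return.
    """

    trial: int
    partner_return: float
    hi_rating: float
    si_rating: float

    def __post_init__(self) -> None:
        if self.partner_return not in (0.0, 0.5):
            raise ValueError(f"partner_return must be 0 or 0.5, got {self.partner_return}")
        for name in ("hi_rating", "si_rating"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass(frozen=True)
class PRLEnvironment:
    """Reward schedule of the three-option reversal task.

    Rewards are drawn conditionally on the chosen option, independently per
    trial, with the block-appropriate success probability.
    """

    n_trials: int = 60
    reversal_trial: int = 30
    reward_probs_block1: tuple[float, float, float] = (0.8, 0.5, 0.2)
    reward_win: float = REWARD_WIN
    reward_loss: float = REWARD_LOSS

    def __post_init__(self) -> None:
        if sorted(self.reward_probs_block1) != [0.2, 0.5, 0.8]:
            # non-standard schedules are allowed but the rotation is only
            # defined for permutations of the canonical triple
            if any(not 0.0 <= p <= 1.0 for p in self.reward_probs_block1):
                raise ValueError("reward probabilities must lie in [0, 1]")

    @property
    def reward_probs_block2(self) -> tuple[float, float, float]:
        """Block-2 probabilities under the low->high, high->even, even->low rotation."""
        return tuple(_ROTATION.get(p, p) for p in self.reward_probs_block1)

    def reward_probs(self, trial: int) -> tuple[float, float, float]:
        """Per-option win probabilities in force on ``trial`` (1-based)."""
        if not 1 <= trial <= self.n_trials:
            raise ValueError(f"trial must lie in [1, {self.n_trials}], got {trial}")
        if trial <= self.reversal_trial:
            return self.reward_probs_block1
        return self.reward_probs_block2


@dataclass(frozen=True)
class DGEnvironment:
    """Partner policy of the repeated-reversal Dictator game."""

    n_trials: int = 20
    reversal_trial: int = 10
    condition: Literal["initially_fair", "initially_unfair"] = "initially_unfair"
    p_unfair_block1: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("initially_fair", "initially_unfair"):
            raise ValueError(f"unknown condition {self.condition!r}")
        p = self.p_unfair_block1
        if p is not None and not 0.0 <= p <= 1.0:
            raise ValueError(f"p_unfair_block1 must lie in [0, 1], got {p}")

    @property
    def _p1(self) -> float:
        if self.p_unfair_block1 is not None:
            return self.p_unfair_block1
        return 0.8 if self.condition == "initially_unfair" else 0.2

    def p_unfair(self, trial: int) -> float:
        """Probability of an unfair return (r = 0) on ``trial`` (1-based)."""
        if not 1 <= trial <= self.n_trials:
            raise ValueError(f"trial must lie in [1, {self.n_trials}], got {trial}")
        return self._p1 if trial <= self.reversal_trial else 1.0 - self._p1


def sample_prl_outcome(
    env: PRLEnvironment, trial: int, choice: int, rng: np.random.Generator
) -> float:
    """Draw the points outcome for choosing ``choice`` on ``trial``."""
    if choice not in (1, 2, 3):
        raise ValueError(f"choice must be in {{1,2,3}}, got {choice}")
    p = env.reward_probs(trial)[choice - 1]
    return env.reward_win if rng.random() < p else env.reward_loss


def sample_dg_return(env: DGEnvironment, trial: int, rng: np.random.Generator) -> float:
    """Draw the partner's return (0 = keep, 0.5 = fair split) on ``trial``."""
    return 0.0 if rng.random() < env.p_unfair(trial) else 0.5


def sample_dg_returns(env: DGEnvironment, rng: np.random.Generator) -> np.ndarray:
    """Draw the full return stream for one participant."""
    return np.array(
        [sample_dg_return(env, t, rng) for t in range(1, env.n_trials + 1)]
    )


def validate_prl_records(records: Sequence[TrialRecordPRL]) -> None:
    """Check that trial indices are strictly increasing and contiguous from 1."""
    trials = [r.trial for r in records]
    if trials != list(range(1, len(records) + 1)):
        raise ValueError("PRL records must cover contiguous trials starting at 1")


def validate_dg_records(records: Sequence[TrialRecordDG]) -> None:
    trials = [r.trial for r in records]
    if trials != list(range(1, len(records) + 1)):
        raise ValueError("DG records must cover contiguous trials starting at 1")
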