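"""Model-agnostic behavioural statistics and permutation correlations.

Win-switch rate: of the trials on which the participant was rewarded (+10)
and a next trial exists in scope, the fraction followed by choosing a
different option.  Lose-stay rate: of the trials with a loss (-5), the
fraction followed by repeating the same option.  Scopes split the task at
the reversal; the transition from trial 30 to 31 is attributed to the
pre-reversal scope, since the feedback that drove it arrived pre-reversal.

The permutation engine computes a Spearman correlation and a two-sided
permutation p-value with add-one correction,
p = (1 + #{|rho_null| >= |rho_obs|}) / (B + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tasks import PRLEnvironment, TrialRecordPRL

Scope = str  # {"all_trials", "pre_reversal", "post_reversal"}


@dataclass(frozen=True)
class SwitchStats:
    participant_id: str
    scope: Scope
    win_switch_rate: Optional[float]
    lose_stay_rate: Optional[float]
    n_wins: int
    n_losses: int


def _scope_pairs(n: int, scope: Scope, reversal_trial: int) -> range:
    """1-based feedback-trial indices t whose (t, t+1) transition is in scope."""
    if scope == "all_trials":
        return range(1, n)
    if scope == "pre_reversal":
        return range(1, min(reversal_trial, n - 1) + 1)
    if scope == "post_reversal":
        return range(reversal_trial + 1, n)
    raise ValueError(f"unknown scope {scope!r}")


def switch_stats(
    data: Sequence[TrialRecordPRL],
    scope: Scope = "all_trials",
    participant_id: str = "0",
    reversal_trial: int = 30,
) -> SwitchStats:
    """Win-switch and lose-stay rates over the requested scope.

    Rates are ``None`` (missing, not zero) when no eligible feedback trial
    exists in scope.
    """
    if len(data) < 2:
        raise ValueError("need at least two trials to compute switch statistics")
    n_wins = n_losses = wins_switched = losses_stayed = 0
    for t in _scope_pairs(len(data), scope, reversal_trial):
        cur, nxt = data[t - 1], data[t]
        if cur.reward > 0:
            n_wins += 1
            if nxt.choice != cur.choice:
                wins_switched += 1
        else:
            n_losses += 1
            if nxt.choice == cur.choice:
                losses_stayed += 1
    return SwitchStats(
        participant_id=participant_id,
        scope=scope,
        win_switch_rate=wins_switched / n_wins if n_wins else None,
        lose_stay_rate=losses_stayed / n_losses if n_losses else None,
        n_wins=n_wins,
        n_losses=n_losses,
    )


def win_switch_rate(data, scope: Scope = "all_trials", **kw) -> SwitchStats:
    return switch_stats(data, scope, **kw)


def lose_stay_rate(data, scope: Scope = "all_trials", **kw) -> SwitchStats:
    return switch_stats(data, scope, **kw)


def choice_proportions(
    data: Sequence[TrialRecordPRL], env: PRLEnvironment
) -> pd.DataFrame:
    """Per-block fractions of choices on the best (0.8), even (0.5) and worst
    (0.2) option under that block's contingency mapping."""
    labels = {0.8: "best", 0.5: "even", 0.2: "worst"}
    counts = {1: {"best": 0, "even": 0, "worst": 0},
              2: {"best": 0, "even": 0, "worst": 0}}
    totals = {1: 0, 2: 0}
    for rec in data:
        block = 1 if rec.trial <= env.reversal_trial else 2
        p = env.reward_probs(rec.trial)[rec.choice - 1]
        counts[block][labels[p]] += 1
        totals[block] += 1
    rows = []
    for block in (1, 2):
        n = totals[block]
        rows.append(
            {"block": block, "n_trials": n,
             **{lab: (counts[block][lab] / n if n else np.nan)
                for lab in ("best", "even", "worst")}}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PermutationResult:
    rho: float
    n_permutations: int
    p_value: float
    null_draws: np.ndarray
    seed: int


def permutation_spearman(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Spearman rho with a permutation null built by shuffling ``y``.

    Two-sided with add-one correction; the p-value is invariant to any
    strictly monotone transform of either input.  Raises on constant input,
    where rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    if x.size < 10:
        raise ValueError("need at least 10 paired observations")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    sx = math.sqrt((rx * rx).sum())
    sy = math.sqrt((ry * ry).sum())
    if sx == 0 or sy == 0:
        raise ValueError("rank correlation undefined for a constant input")
    rho = float(rx @ ry / (sx * sy))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_permutations, 1)), axis=1)
    null = perms @ rx / (sx * sy)
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(rho))) / (n_permutations + 1.0)
    return PermutationResult(rho, n_permutations, float(p), null, seed)
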