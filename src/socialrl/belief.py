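"""Grid-based Bayesian belief model of social attribution.

The participant maintains a joint probability distribution over two latent
attributes of their game partner — harmful intent (HI) and self-interest
(SI) — each discretised into Nb = 9 Likert-like bins, from bin 1 ("totally
altruistic") to bin 9 ("totally antisocial").

Components:

* Priors: each marginal is a binomial pmf Binomial(Nb - 1, p) raised to an
  uncertainty exponent u and renormalised.  u > 1 sharpens the prior around
  its mode, u < 1 blunts it, u = 0 is uniform.  The joint prior is the
  product of the two marginals.
* Policy map: the participant assumes the partner returns nothing (r = 0)
  with probability sigmoid(w0 + wHI*(HI - 5) + wSI*(SI - 5)) given attributes
  (HI, SI); a fair split (r = 0.5) has the complementary probability.
* Update: exact Bayes on the 81-cell grid after each observed return.
* Emission: the reported attribution pair is sampled from (or scored
  against) a blunted copy of the posterior, p_hat proportional to
  p^(1/u_pi) + xi, where u_pi is the policy-uncertainty exponent and
  xi = 0.02 / Nb^2 is a small fixed lapse.  The unblunted posterior
  propagates to the next trial (configurable).
* Reset: between trials 10 and 11 (the covert policy reversal) the prior
  for the second block is a convex mixture (1 - eta) * initial prior +
  eta * current posterior.  A two-eta variant mixes the HI and SI marginals
  with separate weights and rebuilds the joint as their product.

Ratings on the 0-100 scale map to bins by equal-width binning; simulation
reports bin centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, gammaln

from .tasks import DGEnvironment, TrialRecordDG, sample_dg_return

NB = 9
#: Small fixed emission lapse, 0.02 / Nb^2; never fitted.
XI = 0.02 / NB**2

# Default policy-map constants for the "fixed-map" model variants, in which
# w0/wHI/wSI are not fitted.  Values sit near population-typical estimates
# for this task (intercept about -1, shallow positive sensitivities).
FIXED_POLICY_MAP = {"w0": -1.0, "w_hi": 0.1, "w_si": 0.1}


@dataclass(frozen=True)
class SocialBeliefParams:
    """Parameter bundle for the belief-based social attribution family.

    ``eta_dg`` mixes the joint belief at the reversal (one-eta variant);
    ``eta_hi`` / ``eta_si`` mix the marginals separately (two-eta variant).
    Leave all three ``None`` for the no-reset variant.
    """

    p_hi0: float
    u_hi0: float
    p_si0: float
    u_si0: float
    u_pi: float
    w0: float
    w_hi: float
    w_si: float
    eta_dg: Optional[float] = None
    eta_hi: Optional[float] = None
    eta_si: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("p_hi0", "p_si0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("u_hi0", "u_si0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.u_pi > 0:
            raise ValueError(f"u_pi must be strictly positive, got {self.u_pi}")
        if self.w_hi < 0 or self.w_si < 0:
            raise ValueError("policy sensitivities w_hi, w_si must be >= 0")
        for name in ("eta_dg", "eta_hi", "eta_si"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.eta_dg is not None and (self.eta_hi is not None or self.eta_si is not None):
            raise ValueError("use either a joint eta_dg or marginal eta_hi/eta_si, not both")


@dataclass(frozen=True)
class ModelSpecSocial:
    """A belief-based spec: how many reset weights, free or fixed policy map."""

    model_id: str
    n_eta: int
    policy_free: bool
    fixed_policy: dict[str, float] = field(default_factory=lambda: dict(FIXED_POLICY_MAP))

    def __post_init__(self) -> None:
        if self.n_eta not in (0, 1, 2):
            raise ValueError(f"n_eta must be 0, 1 or 2, got {self.n_eta}")

    @property
    def free(self) -> tuple[str, ...]:
        names = ["p_hi0", "u_hi0", "p_si0", "u_si0", "u_pi"]
        if self.policy_free:
            names += ["w0", "w_hi", "w_si"]
        if self.n_eta == 1:
            names.append("eta_dg")
        elif self.n_eta == 2:
            names += ["eta_hi", "eta_si"]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def build_params(self, values: dict[str, float]) -> SocialBeliefParams:
        missing = set(self.free) - set(values)
        if missing:
            raise ValueError(f"missing free parameters: {sorted(missing)}")
        merged = {} if self.policy_free else dict(self.fixed_policy)
        merged.update({k: values[k] for k in self.free})
        return SocialBeliefParams(**merged)


def binomial_power_prior(p: float, u: float, nb: int = NB) -> np.ndarray:
    """Binomial(nb - 1, p) pmf raised to the power u, renormalised.

    Bins 1..nb correspond to binomial counts k = 0..nb-1.  u = 0 yields the
    uniform distribution; p = 0 or 1 a point mass at the first/last bin.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if nb < 2:
        raise ValueError(f"nb must be >= 2, got {nb}")
    if u < 0:
        raise ValueError(f"u must be non-negative, got {u}")
    if u == 0:
        return np.full(nb, 1.0 / nb)
    n = nb - 1
    if p == 0.0 or p == 1.0:
        out = np.zeros(nb)
        out[n if p == 1.0 else 0] = 1.0
        return out
    k = np.arange(nb)
    log_binom = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    logw = u * (log_binom + k * math.log(p) + (n - k) * math.log1p(-p))
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def initial_joint_belief(params: SocialBeliefParams, nb: int = NB) -> np.ndarray:
    """Outer product of the HI and SI binomial-power priors; shape (nb, nb)."""
    hi = binomial_power_prior(params.p_hi0, params.u_hi0, nb)
    si = binomial_power_prior(params.p_si0, params.u_si0, nb)
    return np.outer(hi, si)


def build_policy_map(
    w0: float, w_hi: float, w_si: float, nb: int = NB
) -> np.ndarray:
    """P(r = 0 | HI, SI) as a logistic in bin-centred attributes.

    Entry [i, j] is the unfair-return probability for HI bin i+1, SI bin j+1;
    both attributes are centred at the middle bin (nb + 1) / 2.
    """
    centred = np.arange(1, nb + 1) - (nb + 1) / 2.0
    return expit(w0 + w_hi * centred[:, None] + w_si * centred[None, :])


def belief_update(prior: np.ndarray, partner_return: float, p_unfair_map: np.ndarray) -> np.ndarray:
    """Exact Bayes on the grid for one observed return."""
    like = p_unfair_map if partner_return == 0.0 else 1.0 - p_unfair_map
    post = like * prior
    total = post.sum()
    if not total > 0:
        raise FloatingPointError("posterior has zero total mass")
    return post / total


def blunt_for_emission(belief: np.ndarray, u_pi: float, xi: float = XI) -> np.ndarray:
    """Emission distribution: p_hat proportional to p^(1/u_pi) + xi."""
    if not u_pi > 0:
        raise ValueError(f"u_pi must be strictly positive, got {u_pi}")
    p = belief ** (1.0 / u_pi) + xi
    return p / p.sum()


def reset_beliefs_dg(prior0: np.ndarray, posterior: np.ndarray, eta_dg: float) -> np.ndarray:
    """Block-2 prior: (1 - eta) * initial prior + eta * carried posterior."""
    return (1.0 - eta_dg) * prior0 + eta_dg * posterior


def reset_beliefs_dg_two_eta(
    prior0: np.ndarray, posterior: np.ndarray, eta_hi: float, eta_si: float
) -> np.ndarray:
    """Two-eta reset: mix the HI and SI marginals separately, rebuild the joint.

    The algebra of the two-weight variant is a documented reconstruction: the
    joint is re-formed as the product of the independently mixed marginals.
    """
    hi0, si0 = prior0.sum(axis=1), prior0.sum(axis=0)
    hi1, si1 = posterior.sum(axis=1), posterior.sum(axis=0)
    hi = (1.0 - eta_hi) * hi0 + eta_hi * hi1
    si = (1.0 - eta_si) * si0 + eta_si * si1
    return np.outer(hi, si)


def rating_to_bin(rating: float, nb: int = NB) -> int:
    """Map a 0-100 rating to its equal-width bin in 1..nb."""
    if not 0.0 <= rating <= 100.0:
        raise ValueError(f"rating must lie in [0, 100], got {rating}")
    return min(nb, int(rating * nb / 100.0) + 1)


def bin_to_rating(b: int, nb: int = NB) -> float:
    """Centre of bin ``b`` on the 0-100 scale."""
    if not 1 <= b <= nb:
        raise ValueError(f"bin must lie in [1, {nb}], got {b}")
    return (b - 0.5) * 100.0 / nb


def _apply_reset(
    prior0: np.ndarray, belief: np.ndarray, params: SocialBeliefParams
) -> np.ndarray:
    if params.eta_dg is not None:
        return reset_beliefs_dg(prior0, belief, params.eta_dg)
    if params.eta_hi is not None or params.eta_si is not None:
        eh = params.eta_hi if params.eta_hi is not None else 1.0
        es = params.eta_si if params.eta_si is not None else 1.0
        return reset_beliefs_dg_two_eta(prior0, belief, eh, es)
    return belief


def _social_loglik_core(
    returns: np.ndarray,
    hi_idx: np.ndarray,
    si_idx: np.ndarray,
    params: SocialBeliefParams,
    reversal_trial: int,
    xi: float,
    nb: int,
    propagate_blunted: bool,
) -> float:
    """Inner recursion on pre-binned arrays (0-based bin indices)."""
    prior0 = initial_joint_belief(params, nb)
    like_unfair = build_policy_map(params.w0, params.w_hi, params.w_si, nb)
    like_fair = 1.0 - like_unfair
    belief = prior0
    inv_u = 1.0 / params.u_pi
    ll = 0.0
    for t in range(returns.size):
        if t == reversal_trial:
            belief = _apply_reset(prior0, belief, params)
        post = (like_unfair if returns[t] == 0.0 else like_fair) * belief
        tot = post.sum()
        if not tot > 0:
            raise FloatingPointError(f"posterior has zero mass at trial {t + 1}")
        post /= tot
        belief = post
        emit = post**inv_u
        emit += xi
        cell = emit[hi_idx[t], si_idx[t]] / emit.sum()
        if not cell > 0 or not np.isfinite(cell):
            raise FloatingPointError(
                f"non-finite or zero emission probability at trial {t + 1}"
            )
        ll += math.log(cell)
        if propagate_blunted:
            belief = emit / emit.sum()
    return ll


def _records_to_arrays(
    data: Sequence[TrialRecordDG], nb: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    returns = np.array([r.partner_return for r in data])
    hi_idx = np.array([rating_to_bin(r.hi_rating, nb) - 1 for r in data])
    si_idx = np.array([rating_to_bin(r.si_rating, nb) - 1 for r in data])
    return returns, hi_idx, si_idx


def social_loglik(
    data: Sequence[TrialRecordDG],
    params: SocialBeliefParams,
    reversal_trial: int = 10,
    xi: float = XI,
    nb: int = NB,
    propagate_blunted: bool = False,
) -> float:
    """Summed log-likelihood of a rating sequence under the belief model.

    Per trial: update the belief on the observed return, blunt it for
    emission, score the observed (HI bin, SI bin) cell.  The reset mixture
    is applied between trials ``reversal_trial`` and ``reversal_trial + 1``.
    By default the unblunted posterior propagates; set ``propagate_blunted``
    to carry the emission distribution instead (the model description is
    ambiguous on this point, so it is exposed as a switch).
    """
    returns, hi_idx, si_idx = _records_to_arrays(data, nb)
    return _social_loglik_core(
        returns, hi_idx, si_idx, params, reversal_trial, xi, nb, propagate_blunted
    )


def simulate_social_agent(
    env: DGEnvironment,
    params: SocialBeliefParams,
    seed: int | np.random.Generator,
    xi: float = XI,
    nb: int = NB,
    propagate_blunted: bool = False,
) -> list[TrialRecordDG]:
    """Forward-simulate one participant: returns from the environment, rating
    bins sampled from the blunted emission grid, reported as bin centres."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prior0 = initial_joint_belief(params, nb)
    pmap = build_policy_map(params.w0, params.w_hi, params.w_si, nb)
    belief = prior0
    records: list[TrialRecordDG] = []
    for t in range(1, env.n_trials + 1):
        if t == env.reversal_trial + 1:
            belief = _apply_reset(prior0, belief, params)
        r = sample_dg_return(env, t, rng)
        belief = belief_update(belief, r, pmap)
        emit = blunt_for_emission(belief, params.u_pi, xi)
        flat_idx = int(rng.choice(nb * nb, p=emit.ravel()))
        hi_bin, si_bin = divmod(flat_idx, nb)
        records.append(
            TrialRecordDG(
                trial=t,
                partner_return=r,
                hi_rating=bin_to_rating(hi_bin + 1, nb),
                si_rating=bin_to_rating(si_bin + 1, nb),
            )
        )
        if propagate_blunted:
            belief = emit
    return records


def belief_trajectory(
    data: Sequence[TrialRecordDG],
    params: SocialBeliefParams,
    participant_id: str = "0",
    reversal_trial: int = 10,
    xi: float = XI,
    nb: int = NB,
):
    """Long-format emission-belief trajectory for plotting.

    One row per (trial, HI bin, SI bin) with the blunted emission
    probability in force when the trial's ratings were given.  Columns:
    ``participant_id, trial, hi_bin, si_bin, prob``.
    """
    import pandas as pd

    prior0 = initial_joint_belief(params, nb)
    pmap = build_policy_map(params.w0, params.w_hi, params.w_si, nb)
    belief = prior0
    rows = []
    hi_idx, si_idx = np.meshgrid(np.arange(1, nb + 1), np.arange(1, nb + 1),
                                 indexing="ij")
    for rec in data:
        if rec.trial == reversal_trial + 1:
            belief = _apply_reset(prior0, belief, params)
        belief = belief_update(belief, rec.partner_return, pmap)
        emit = blunt_for_emission(belief, params.u_pi, xi)
        rows.append(
            pd.DataFrame(
                {"participant_id": participant_id, "trial": rec.trial,
                 "hi_bin": hi_idx.ravel(), "si_bin": si_idx.ravel(),
                 "prob": emit.ravel()}
            )
        )
    return pd.concat(rows, ignore_index=True)


_SOCIAL_SPECS: tuple[ModelSpecSocial, ...] = (
    ModelSpecSocial("bb_fixed_0eta", n_eta=0, policy_free=False),
    ModelSpecSocial("bb_fixed_1eta", n_eta=1, policy_free=False),
    ModelSpecSocial("bb_fixed_2eta", n_eta=2, policy_free=False),
    ModelSpecSocial("bb_free_0eta", n_eta=0, policy_free=True),
    ModelSpecSocial("bb_free_1eta", n_eta=1, policy_free=True),
    ModelSpecSocial("bb_free_2eta", n_eta=2, policy_free=True),
)

WINNING_SOCIAL_MODEL = "bb_free_1eta"


def social_model_space() -> list[ModelSpecSocial]:
    """The registry of six belief-based specs ({fixed, free map} x {0,1,2 eta})."""
    return list(_SOCIAL_SPECS)


def get_social_spec(model_id: str) -> ModelSpecSocial:
    for spec in _SOCIAL_SPECS:
        if spec.model_id == model_id:
            return spec
    valid = ", ".join(s.model_id for s in _SOCIAL_SPECS)
    raise KeyError(f"unknown social model {model_id!r}; valid ids: {valid}")
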