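"""Associative comparator family for the social task.

Instead of holding a belief distribution over partner attributes, these
models track a single cached "expected social value" (ESV) latent on the
return scale [0, 0.5], updated trial-by-trial with a delta rule.  Each
attribution (harmful intent, self-interest) is predicted on the 0-1 scale
by a logistic mapping of the centred latent, and observed ratings (divided
by 100) are scored with Gaussian noise of standard deviation sigma.

The family spans {no, one, two} reset weights applied to the latent at the
policy reversal and {shared, separate} attribution mappings, plus a
dual-learning-rate variant in which the two attributions track the returns
with their own rates — a reconstruction of the comparator family used in
model comparison against the belief-based models, with the structural
choices (latent centred at 0.25, one shared sigma) exposed here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import math

from scipy.special import expit

from .tasks import TrialRecordDG

#: Centre of the return scale: predictions are logistic in (esv - ESV_CENTRE).
ESV_CENTRE = 0.25
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SocialAssocParams:
    """Parameters of the expected-social-value attribution model."""

    esv0: float
    alpha: float
    hi_icpt: float
    hi_slope: float
    si_icpt: float
    si_slope: float
    sigma: float
    alpha_si: Optional[float] = None
    eta_hi: Optional[float] = None
    eta_si: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.esv0 <= 0.5:
            raise ValueError(f"esv0 must lie in [0, 0.5], got {self.esv0}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.alpha_si is not None and not 0.0 <= self.alpha_si <= 1.0:
            raise ValueError(f"alpha_si must lie in [0, 1], got {self.alpha_si}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be strictly positive, got {self.sigma}")
        for name in ("eta_hi", "eta_si"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ModelSpecAssoc:
    """Member of the associative space.

    ``n_eta``: reset weights at the reversal (0, 1 shared, or 2 separate).
    ``shared_map``: one intercept/slope pair serves both attributions.
    ``dual_alpha``: separate learning rates for the HI- and SI-driving
    latents (they then diverge from trial 1, not only at the reversal).
    ``bin_likelihood``: score ratings as truncated-Gaussian bin masses on
    the same 9-bin grid the belief models emit over, instead of continuous
    densities.  Within-family comparisons can use either; comparisons
    against the belief-based family must use bin masses so both BICs sum
    probabilities of the same discrete observables.
    """

    model_id: str
    n_eta: int
    shared_map: bool
    dual_alpha: bool = False
    bin_likelihood: bool = False

    @property
    def free(self) -> tuple[str, ...]:
        names = ["esv0", "alpha"]
        if self.dual_alpha:
            names.append("alpha_si")
        if self.shared_map:
            names += ["hi_icpt", "hi_slope"]
        else:
            names += ["hi_icpt", "hi_slope", "si_icpt", "si_slope"]
        if self.n_eta == 1:
            names.append("eta_hi")
        elif self.n_eta == 2:
            names += ["eta_hi", "eta_si"]
        names.append("sigma")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def build_params(self, values: dict[str, float]) -> SocialAssocParams:
        missing = set(self.free) - set(values)
        if missing:
            raise ValueError(f"missing free parameters: {sorted(missing)}")
        merged = dict(values)
        if self.shared_map:
            merged["si_icpt"] = merged["hi_icpt"]
            merged["si_slope"] = merged["hi_slope"]
        if self.n_eta == 1:
            merged["eta_si"] = merged["eta_hi"]
        return SocialAssocParams(**merged)


def esv_update(esv: float, observed_return: float, alpha: float) -> float:
    """Delta-rule update of the latent: esv <- esv + alpha * (r - esv)."""
    return esv + alpha * (observed_return - esv)


def predict_attributions(
    esv_hi: float, esv_si: float, params: SocialAssocParams
) -> tuple[float, float]:
    """Predicted (HI, SI) attributions on the 0-1 scale from the latent(s)."""
    hi = expit(params.hi_icpt + params.hi_slope * (esv_hi - ESV_CENTRE))
    si = expit(params.si_icpt + params.si_slope * (esv_si - ESV_CENTRE))
    return float(hi), float(si)


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _log_bin_mass(rating01: float, pred: float, sig: float, nb: int) -> float:
    """Log probability of the rating's bin under a [0,1]-truncated Gaussian."""
    b = min(nb - 1, int(rating01 * nb))
    lo, hi = b / nb, (b + 1) / nb
    mass = _phi((hi - pred) / sig) - _phi((lo - pred) / sig)
    total = _phi((1.0 - pred) / sig) - _phi((0.0 - pred) / sig)
    return math.log(max(mass, 1e-300)) - math.log(max(total, 1e-300))


def assoc_loglik(
    data: Sequence[TrialRecordDG],
    params: SocialAssocParams,
    reversal_trial: int = 10,
    bin_likelihood: bool = False,
    nb: int = 9,
) -> float:
    """Log-likelihood of the observed rating pairs.

    A single latent drives both attributions until the reversal; separate
    reset weights (eta_hi, eta_si) let the two streams diverge afterwards.
    Per trial the latent is updated on the observed return and both
    attributions are scored at the resulting predictions — as Gaussian
    densities of rating/100 by default, or as truncated-Gaussian bin masses
    on the ``nb``-bin grid when ``bin_likelihood`` is set (required for
    information-criterion comparison against the belief-based family).
    """
    esv_hi = esv_si = params.esv0
    sig = params.sigma
    log_norm = -math.log(sig) - _LOG_SQRT_2PI
    inv2s2 = 0.5 / (sig * sig)
    ll = 0.0
    for rec in data:
        if rec.trial == reversal_trial + 1:
            if params.eta_hi is not None:
                esv_hi = (1.0 - params.eta_hi) * params.esv0 + params.eta_hi * esv_hi
            if params.eta_si is not None:
                esv_si = (1.0 - params.eta_si) * params.esv0 + params.eta_si * esv_si
        esv_hi = esv_update(esv_hi, rec.partner_return, params.alpha)
        esv_si = esv_update(
            esv_si, rec.partner_return,
            params.alpha_si if params.alpha_si is not None else params.alpha,
        )
        hi_pred, si_pred = predict_attributions(esv_hi, esv_si, params)
        if bin_likelihood:
            ll += _log_bin_mass(rec.hi_rating / 100.0, hi_pred, sig, nb)
            ll += _log_bin_mass(rec.si_rating / 100.0, si_pred, sig, nb)
        else:
            rh = rec.hi_rating / 100.0 - hi_pred
            rs = rec.si_rating / 100.0 - si_pred
            ll += 2.0 * log_norm - inv2s2 * (rh * rh + rs * rs)
    return ll


_ASSOC_SPECS: tuple[ModelSpecAssoc, ...] = (
    ModelSpecAssoc("as_shared_0eta", n_eta=0, shared_map=True),
    ModelSpecAssoc("as_shared_1eta", n_eta=1, shared_map=True),
    ModelSpecAssoc("as_shared_2eta", n_eta=2, shared_map=True),
    ModelSpecAssoc("as_sep_0eta", n_eta=0, shared_map=False),
    ModelSpecAssoc("as_sep_1eta", n_eta=1, shared_map=False),
    ModelSpecAssoc("as_sep_2eta", n_eta=2, shared_map=False),
    ModelSpecAssoc("as_dual_alpha", n_eta=0, shared_map=False, dual_alpha=True),
)


def assoc_model_space(bin_likelihood: bool = False) -> list[ModelSpecAssoc]:
    """The registry of seven associative specs.

    Pass ``bin_likelihood=True`` to obtain the variants whose ratings are
    scored as 9-bin masses, for comparison against belief-based models.
    """
    if not bin_likelihood:
        return list(_ASSOC_SPECS)
    return [replace(s, bin_likelihood=True) for s in _ASSOC_SPECS]


def get_assoc_spec(model_id: str) -> ModelSpecAssoc:
    for spec in _ASSOC_SPECS:
        if spec.model_id == model_id:
            return spec
    valid = ", ".join(s.model_id for s in _ASSOC_SPECS)
    raise KeyError(f"unknown associative model {model_id!r}; valid ids: {valid}")
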