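"""Per-participant MAP fitting and information-criterion model comparison.

Fitting maximises the log posterior — the model log-likelihood penalised by
weak, range-restricting priors — with a three-stage pipeline:

1. a Latin-hypercube scan of the legal parameter box,
2. short simulated-annealing chains started from the best scan points
   (Gaussian proposals in an unconstrained transformed space, geometric
   temperature schedule),
3. local polish with Nelder-Mead followed by L-BFGS-B.

All parameters are given finite boxes and optimised through a scaled-logit
transform, so every proposal is automatically legal.  The priors are weak:
Beta(1.2, 1.2) on unit-interval parameters, Gamma(shape 2, scale 3) on
positive ones, Normal(0, 5) (or half-normal) on policy weights.

Model comparison uses BIC = -2 LL + k ln(n) and AIC = -2 LL + 2k with one
observation per trial (60 for the reversal task, 20 for the social task,
where a trial contributes one joint rating-pair observation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import associative, belief, rl

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# priors (closed-form log densities; cheap enough for inner optimisation loops)

class BetaPrior:
    """Beta(a, b) stretched onto [lo, hi]."""

    def __init__(self, a: float = 1.2, b: float = 1.2):
        self.a, self.b = a, b
        self._lognorm = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)

    def logpdf(self, x: float, lo: float, hi: float) -> float:
        z = (x - lo) / (hi - lo)
        if not 0.0 < z < 1.0:
            return -math.inf
        return (
            self._lognorm
            + (self.a - 1.0) * math.log(z)
            + (self.b - 1.0) * math.log1p(-z)
            - math.log(hi - lo)
        )


class GammaPrior:
    """Gamma(shape, scale) on the positive half-line."""

    def __init__(self, shape: float = 2.0, scale: float = 3.0):
        self.shape, self.scale = shape, scale
        self._lognorm = -math.lgamma(shape) - shape * math.log(scale)

    def logpdf(self, x: float, lo: float, hi: float) -> float:
        if x <= 0:
            return -math.inf
        return self._lognorm + (self.shape - 1.0) * math.log(x) - x / self.scale


class NormalPrior:
    def __init__(self, mu: float = 0.0, sd: float = 5.0, half: bool = False):
        self.mu, self.sd, self.half = mu, sd, half

    def logpdf(self, x: float, lo: float, hi: float) -> float:
        z = (x - self.mu) / self.sd
        lp = -0.5 * z * z - math.log(self.sd) - _LOG_SQRT_2PI
        return lp + math.log(2.0) if self.half else lp


@dataclass(frozen=True)
class ParamDef:
    """Name, legal box, and weak prior for one free parameter."""

    name: str
    lo: float
    hi: float
    prior: BetaPrior | GammaPrior | NormalPrior

    def logprior(self, x: float) -> float:
        if not self.lo <= x <= self.hi:
            return -math.inf
        return self.prior.logpdf(x, self.lo, self.hi)


_UNIT = lambda name: ParamDef(name, 0.0, 1.0, BetaPrior())

PRL_PARAM_DEFS: dict[str, ParamDef] = {
    "tau": ParamDef("tau", 1e-3, 50.0, GammaPrior()),
    **{n: _UNIT(n) for n in ("lam1", "lam2", "s", "phi", "eta_pr", "zeta")},
}

SOCIAL_PARAM_DEFS: dict[str, ParamDef] = {
    "p_hi0": _UNIT("p_hi0"),
    "p_si0": _UNIT("p_si0"),
    "u_hi0": ParamDef("u_hi0", 1e-3, 20.0, GammaPrior()),
    "u_si0": ParamDef("u_si0", 1e-3, 20.0, GammaPrior()),
    "u_pi": ParamDef("u_pi", 1e-3, 20.0, GammaPrior()),
    "w0": ParamDef("w0", -10.0, 10.0, NormalPrior()),
    "w_hi": ParamDef("w_hi", 0.0, 5.0, NormalPrior(half=True)),
    "w_si": ParamDef("w_si", 0.0, 5.0, NormalPrior(half=True)),
    "eta_dg": _UNIT("eta_dg"),
    "eta_hi": _UNIT("eta_hi"),
    "eta_si": _UNIT("eta_si"),
}

ASSOC_PARAM_DEFS: dict[str, ParamDef] = {
    "esv0": ParamDef("esv0", 0.0, 0.5, BetaPrior()),
    "alpha": _UNIT("alpha"),
    "alpha_si": _UNIT("alpha_si"),
    "hi_icpt": ParamDef("hi_icpt", -10.0, 10.0, NormalPrior()),
    "si_icpt": ParamDef("si_icpt", -10.0, 10.0, NormalPrior()),
    "hi_slope": ParamDef("hi_slope", -20.0, 20.0, NormalPrior()),
    "si_slope": ParamDef("si_slope", -20.0, 20.0, NormalPrior()),
    "sigma": ParamDef("sigma", 1e-3, 1.0, GammaPrior()),
    "eta_hi": _UNIT("eta_hi"),
    "eta_si": _UNIT("eta_si"),
}


# ---------------------------------------------------------------------------
# configuration and results

@dataclass(frozen=True)
class FitConfig:
    """Budget of the grid -> annealing -> polish pipeline."""

    n_grid: int = 200
    n_chains: int = 3
    n_anneal_steps: int = 120
    t_start: float = 1.0
    t_end: float = 0.01
    step_scale: float = 0.6
    polish: bool = True
    nm_maxiter: int = 400

    @classmethod
    def fast(cls) -> "FitConfig":
        """Reduced budget for smoke tests and quick exploration."""
        return cls(n_grid=60, n_chains=1, n_anneal_steps=40, nm_maxiter=150)


@dataclass(frozen=True)
class FitResult:
    """MAP estimate for one participant under one model spec."""

    model_id: str
    participant_id: str
    estimates: dict[str, float]
    loglik: float
    logpost: float
    bic: float
    aic: float
    n_obs: int
    k: int
    converged: bool
    n_restarts: int
    seed: int

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "model_id": self.model_id,
            "loglik": self.loglik,
            "logpost": self.logpost,
            "bic": self.bic,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "k": self.k,
            "converged": self.converged,
            "seed": self.seed,
        }
        row.update(self.estimates)
        return row


# ---------------------------------------------------------------------------
# transforms

def _to_unconstrained(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    z = np.clip((x - lo) / (hi - lo), 1e-12, 1.0 - 1e-12)
    return np.log(z) - np.log1p(-z)


def _to_constrained(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):  # exp overflow saturates to the bound
        return lo + (hi - lo) / (1.0 + np.exp(-z))


def map_objective(
    values: Mapping[str, float],
    loglik_fn: Callable[[Mapping[str, float]], float],
    param_defs: Sequence[ParamDef],
) -> float:
    """Negative log posterior; +inf outside the legal box or on numerical failure."""
    lp = 0.0
    for d in param_defs:
        lp += d.logprior(values[d.name])
        if lp == -math.inf:
            return math.inf
    try:
        ll = loglik_fn(values)
    except FloatingPointError:
        return math.inf
    if not math.isfinite(ll):
        return math.inf
    return -(ll + lp)


def fit_map(
    loglik_fn: Callable[[Mapping[str, float]], float],
    param_defs: Sequence[ParamDef],
    *,
    n_obs: int,
    model_id: str = "model",
    participant_id: str = "0",
    seed: int = 0,
    config: FitConfig | None = None,
) -> FitResult:
    """Maximise the log posterior of ``loglik_fn`` over the free parameters.

    Deterministic for a fixed seed.  ``loglik_fn`` receives a dict of free
    parameter values and returns the summed log-likelihood.
    """
    config = config or FitConfig()
    names = [d.name for d in param_defs]
    k = len(names)
    lo = np.array([d.lo for d in param_defs])
    hi = np.array([d.hi for d in param_defs])
    rng = np.random.default_rng(seed)

    def obj_x(x: np.ndarray) -> float:
        return map_objective(dict(zip(names, x)), loglik_fn, param_defs)

    def obj_z(z: np.ndarray) -> float:
        return obj_x(_to_constrained(z, lo, hi))

    if k == 0:
        ll = loglik_fn({})
        return FitResult(model_id, participant_id, {}, ll, ll,
                         -2 * ll, -2 * ll, n_obs, 0, True, 0, seed)

    # stage 1: space-filling scan of the box (interior only, so priors stay finite)
    sampler = qmc.LatinHypercube(d=k, seed=rng)
    u = 0.002 + 0.996 * sampler.random(config.n_grid)
    grid_x = lo + u * (hi - lo)
    grid_f = np.array([obj_x(x) for x in grid_x])
    order = np.argsort(grid_f)

    best_x = grid_x[order[0]].copy()
    best_f = float(grid_f[order[0]])

    # stage 2: annealing chains from the best scan points
    n_chains = min(config.n_chains, config.n_grid)
    decay = (config.t_end / config.t_start) ** (1.0 / max(config.n_anneal_steps - 1, 1))
    for c in range(n_chains):
        z = _to_unconstrained(grid_x[order[c]], lo, hi)
        f = float(grid_f[order[c]])
        temp = config.t_start
        for _ in range(config.n_anneal_steps):
            prop = z + rng.normal(0.0, config.step_scale * math.sqrt(temp), size=k)
            fp = obj_z(prop)
            if fp < f or rng.random() < math.exp(min(0.0, (f - fp) / temp)):
                z, f = prop, fp
                if f < best_f:
                    best_f = f
                    best_x = _to_constrained(z, lo, hi)
            temp *= decay

    # stage 3: local polish in the transformed space
    converged = math.isfinite(best_f)
    if config.polish and math.isfinite(best_f):
        z0 = _to_unconstrained(best_x, lo, hi)
        res = optimize.minimize(
            obj_z, z0, method="Nelder-Mead",
            options={"maxiter": config.nm_maxiter, "xatol": 1e-5, "fatol": 1e-7},
        )
        if res.fun < best_f:
            best_f, z0 = float(res.fun), res.x
        res2 = optimize.minimize(obj_z, z0, method="L-BFGS-B")
        if res2.fun < best_f:
            best_f, z0 = float(res2.fun), res2.x
        best_x = _to_constrained(np.asarray(z0, dtype=float), lo, hi)
        converged = bool(res.success or res2.success) and math.isfinite(best_f)

    estimates = dict(zip(names, (float(v) for v in best_x)))
    if math.isfinite(best_f):
        try:
            ll = loglik_fn(estimates)
        except FloatingPointError:
            ll = -math.inf
    else:
        ll = -math.inf
        converged = False
    logpost = -best_f
    bic = -2.0 * ll + k * math.log(n_obs)
    aic = -2.0 * ll + 2.0 * k
    return FitResult(
        model_id, participant_id, estimates, ll, logpost, bic, aic,
        n_obs, k, converged, n_chains, seed,
    )


# ---------------------------------------------------------------------------
# task-specific front ends

AnySpec = rl.ModelSpecPRL | belief.ModelSpecSocial | associative.ModelSpecAssoc


def _defs_for(spec: AnySpec) -> list[ParamDef]:
    if isinstance(spec, rl.ModelSpecPRL):
        table = PRL_PARAM_DEFS
    elif isinstance(spec, belief.ModelSpecSocial):
        table = SOCIAL_PARAM_DEFS
    else:
        table = ASSOC_PARAM_DEFS
    return [table[n] for n in spec.free]


def fit_model(
    data,
    spec: AnySpec,
    *,
    participant_id: str = "0",
    seed: int = 0,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one spec (reversal-learning, belief-based, or associative) to one
    participant's trial records."""
    if isinstance(spec, rl.ModelSpecPRL):
        def loglik_fn(values):
            return rl.prl_loglik(data, spec.build_params(values))
    elif isinstance(spec, belief.ModelSpecSocial):
        returns, hi_idx, si_idx = belief._records_to_arrays(data, belief.NB)

        def loglik_fn(values):
            return belief._social_loglik_core(
                returns, hi_idx, si_idx, spec.build_params(values),
                10, belief.XI, belief.NB, False,
            )
    elif isinstance(spec, associative.ModelSpecAssoc):
        def loglik_fn(values):
            return associative.assoc_loglik(
                data, spec.build_params(values),
                bin_likelihood=spec.bin_likelihood,
            )
    else:
        raise TypeError(f"unknown spec type {type(spec).__name__}")
    return fit_map(
        loglik_fn,
        _defs_for(spec),
        n_obs=len(data),
        model_id=spec.model_id,
        participant_id=participant_id,
        seed=seed,
        config=config,
    )


def compare_models(
    data_by_participant: Mapping[str, Sequence],
    specs: Sequence[AnySpec],
    *,
    seed: int = 0,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Fit every spec to every participant and rank by BIC.

    Returns a long table with one row per (participant, model); the row with
    ``best == True`` is the participant's BIC winner, ties broken by fewer
    parameters then lexicographic model id.  Failed fits are kept with
    ``converged == False`` and excluded from ranking.
    """
    if not specs:
        raise ValueError("at least one model spec is required")
    rows = []
    ss = np.random.SeedSequence(seed)
    for (pid, data), child in zip(
        data_by_participant.items(),
        ss.spawn(len(data_by_participant)),
    ):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        fits = [
            fit_model(data, spec, participant_id=str(pid),
                      seed=sub_seed + j, config=config)
            for j, spec in enumerate(specs)
        ]
        ranked = sorted(
            (f for f in fits if math.isfinite(f.bic)),
            key=lambda f: (f.bic, f.k, f.model_id),
        )
        best_id = ranked[0].model_id if ranked else None
        for f in fits:
            row = f.to_row()
            row["best"] = f.model_id == best_id
            rows.append(row)
    return pd.DataFrame(rows)


def best_model_counts(comparison: pd.DataFrame) -> pd.Series:
    """Aggregate: how often each model wins by BIC across participants."""
    return comparison.loc[comparison["best"], "model_id"].value_counts()
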