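"""Synthetic cohorts with the study's covariate and parameter structure.

Participants carry a paranoia score (persecutory-ideation questionnaire
total: integer, zero-heavy, strongly right-tailed; population mean 3.88,
sd 6.18, observed range 0-33) and a fluid-intelligence score (ICAR matrices:
approximately normal, mean 4.96, sd 2.42, range 0-11).  Paranoia is drawn
from a moment-matched negative binomial clipped at the observed maximum;
ICAR from a truncated normal whose location is solved so the truncated mean
hits the target.

Each participant receives generating parameters for both winning models
(the salience + reset + decay reversal-learning model and the free-map
one-eta belief model).  Parameters are drawn on link scales (log for
positive parameters, logit for unit-interval ones) as

    link = mu + sd_link * (slope * z_paranoia + sqrt(1 - slope^2) * noise)

so that the link-scale correlation with standardised paranoia equals the
standardised slope.  Default slopes couple paranoia to decision temperature
(0.13), the strength of priors over harmful intent (0.16), policy
uncertainty (0.17), and the self-interest policy sensitivity (0.15); all
other parameters are uncoupled.  The slopes are stand-ins with the same
sign and magnitude as fitted standardised coefficients, not estimates of a
real generative process.

Both tasks are then simulated from the stored true parameters, giving a
cohort on which every downstream stage (fitting, comparison, statistics,
recovery) can run without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .belief import SocialBeliefParams, simulate_social_agent
from .rl import PRLParams, simulate_prl_agent
from .tasks import DGEnvironment, PRLEnvironment, TrialRecordDG, TrialRecordPRL

#: Link-scale base distributions for the winning reversal-learning model:
#: (link, mu, sd) per parameter.  Means sit at field-typical values (tau
#: around 2 points on the +10/-5 reward scale, moderate learning rates);
#: the spreads deliberately cover the whole psychologically plausible range
#: of each parameter, so cohorts double as recovery-study populations.
PRL_BASE = {
    "tau": ("log", math.log(2.0), 0.7),
    "lam1": ("logit", -0.6, 1.3),
    "s": ("logit", 0.0, 1.5),
    "phi": ("logit", 1.0, 1.3),
    "eta_pr": ("logit", 0.0, 1.6),
}

#: Link-scale base distributions for the winning belief model.  The policy
#: intercept sits near -1 (population-typical); the sensitivity spreads span
#: roughly 0.1-0.9, the range over which simulated attributional flexibility
#: visibly varies.
SOCIAL_BASE = {
    "p_hi0": ("logit", -0.4, 1.2),
    "u_hi0": ("log", math.log(1.5), 0.6),
    "p_si0": ("logit", 0.2, 1.2),
    "u_si0": ("log", math.log(1.5), 0.6),
    "u_pi": ("log", math.log(2.0), 0.6),
    "w0": ("identity", -1.0, 0.6),
    "w_hi": ("log", math.log(0.25), 0.8),
    "w_si": ("log", math.log(0.3), 0.8),
    "eta_dg": ("logit", 0.0, 1.6),
}

DEFAULT_EFFECT_MAP = {"tau": 0.13, "p_hi0": 0.16, "u_pi": 0.17, "w_si": 0.15}

# clip back-transformed draws into the legal boxes used by the fitter
_PARAM_CLIP = {"tau": (1e-3, 50.0), "u_hi0": (1e-3, 20.0), "u_si0": (1e-3, 20.0),
               "u_pi": (1e-3, 20.0), "w_hi": (1e-4, 5.0), "w_si": (1e-4, 5.0),
               "w0": (-10.0, 10.0)}


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 200
    paranoia_mean: float = 3.88
    paranoia_sd: float = 6.18
    paranoia_max: float = 33.0
    icar_mean: float = 4.96
    icar_sd: float = 2.42
    icar_range: tuple[float, float] = (0.0, 11.0)
    effect_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP)
    )
    prl_base: dict = field(default_factory=lambda: dict(PRL_BASE))
    social_base: dict = field(default_factory=lambda: dict(SOCIAL_BASE))
    seed: int = 0

    def __post_init__(self) -> None:
        for name, slope in self.effect_map.items():
            if not -1.0 < slope < 1.0:
                raise ValueError(f"effect slope for {name} must lie in (-1, 1)")


@dataclass
class SyntheticCohort:
    """Covariates, generating parameters, and simulated task data."""

    config: CohortConfig
    covariates: pd.DataFrame
    true_params: pd.DataFrame
    prl_records: dict[str, list[TrialRecordPRL]]
    dg_records: dict[str, list[TrialRecordDG]]


@lru_cache(maxsize=8)
def _nb_solve(mean: float, sd: float, cap: float) -> tuple[float, float]:
    """Negative-binomial (mean, size) whose cap-clipped draw hits the targets."""
    from scipy.stats import nbinom

    ks = np.arange(int(cap))

    def clipped_moments(m: float, size: float) -> tuple[float, float]:
        pmf = nbinom.pmf(ks, size, size / (size + m))
        tail = max(1.0 - pmf.sum(), 0.0)
        vals = np.append(ks, cap)
        probs = np.append(pmf, tail)
        mu = float(vals @ probs)
        var = float(vals**2 @ probs) - mu * mu
        return mu, math.sqrt(max(var, 0.0))

    def gap(x):
        mu, s = clipped_moments(math.exp(x[0]), math.exp(x[1]))
        return [mu - mean, s - sd]

    size0 = mean * mean / (sd * sd - mean)
    sol = optimize.fsolve(
        gap, [math.log(mean), math.log(size0)], full_output=False
    )
    return math.exp(sol[0]), math.exp(sol[1])


def draw_paranoia(n: int, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial paranoia scores, clipped at the observed maximum.

    The underlying (mean, dispersion) are solved so the *clipped* draw
    matches the target moments.
    """
    m, sd = config.paranoia_mean, config.paranoia_sd
    if sd == 0:
        return np.full(n, m)
    if sd * sd <= m:
        raise ValueError(
            f"paranoia variance {sd * sd:.3g} must exceed the mean {m:.3g} "
            "for a negative-binomial draw"
        )
    m_raw, size = _nb_solve(m, sd, config.paranoia_max)
    draws = rng.negative_binomial(size, size / (size + m_raw), size=n).astype(float)
    return np.minimum(draws, config.paranoia_max)


def draw_icar(n: int, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal ICAR scores with the truncated mean at the target."""
    lo, hi = config.icar_range
    sd = config.icar_sd
    if sd == 0:
        return np.full(n, config.icar_mean)

    def mean_gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - config.icar_mean

    loc = brentq(mean_gap, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def draw_covariates(
    config: CohortConfig, rng: np.random.Generator, n: Optional[int] = None
) -> pd.DataFrame:
    """Paranoia and ICAR scores plus the alternating DG condition assignment."""
    n = n if n is not None else config.n_participants
    paranoia = draw_paranoia(n, config, rng)
    icar = draw_icar(n, config, rng)
    condition = np.where(
        np.arange(n) % 2 == 0, "initially_unfair", "initially_fair"
    )
    ids = [f"p{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {"participant_id": ids, "paranoia": paranoia, "icar": icar,
         "condition": condition}
    )


def _back_transform(name: str, link: str, values: np.ndarray) -> np.ndarray:
    if link == "log":
        out = np.exp(values)
    elif link == "logit":
        out = expit(values)
    else:
        out = values
    if name in _PARAM_CLIP:
        lo, hi = _PARAM_CLIP[name]
        out = np.clip(out, lo, hi)
    return out


def draw_parameter_table(
    paranoia: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Generating parameters for every participant, coupled to paranoia.

    Paranoia is standardised against the configured population moments (not
    the realised sample), so the injected link-scale correlation equals the
    configured slope in expectation.
    """
    paranoia = np.asarray(paranoia, dtype=float)
    n = paranoia.size
    sd = config.paranoia_sd if config.paranoia_sd > 0 else 1.0
    z = (paranoia - config.paranoia_mean) / sd
    cols: dict[str, np.ndarray] = {}
    for base in (config.prl_base, config.social_base):
        for name, (link, mu, sd_link) in base.items():
            slope = config.effect_map.get(name, 0.0)
            eps = rng.normal(size=n)
            latent = slope * z + math.sqrt(1.0 - slope * slope) * eps
            cols[name] = _back_transform(name, link, mu + sd_link * latent)
    return pd.DataFrame(cols)


def draw_participant_params(
    paranoia: float, icar: float, config: CohortConfig, rng: np.random.Generator
) -> tuple[PRLParams, SocialBeliefParams]:
    """Single-participant convenience wrapper around the vectorised draw."""
    row = draw_parameter_table(np.array([paranoia]), config, rng).iloc[0]
    return _row_to_params(row)


def _row_to_params(row: pd.Series) -> tuple[PRLParams, SocialBeliefParams]:
    prl = PRLParams(
        tau=row["tau"], lam1=row["lam1"], s=row["s"], phi=row["phi"],
        eta_pr=row["eta_pr"],
    )
    social = SocialBeliefParams(
        p_hi0=row["p_hi0"], u_hi0=row["u_hi0"], p_si0=row["p_si0"],
        u_si0=row["u_si0"], u_pi=row["u_pi"], w0=row["w0"],
        w_hi=row["w_hi"], w_si=row["w_si"], eta_dg=row["eta_dg"],
    )
    return prl, social


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full cohort: covariates, generating parameters, both tasks simulated.

    Deterministic for a fixed ``config.seed``; every participant gets an
    independent child RNG stream, split by task.
    """
    ss = np.random.SeedSequence(config.seed)
    cov_ss, par_ss, task_ss = ss.spawn(3)
    rng_cov = np.random.default_rng(cov_ss)
    rng_par = np.random.default_rng(par_ss)

    covariates = draw_covariates(config, rng_cov)
    params = draw_parameter_table(
        covariates["paranoia"].to_numpy(), config, rng_par
    )
    true_params = pd.concat(
        [covariates[["participant_id"]].reset_index(drop=True), params], axis=1
    )

    prl_env = PRLEnvironment()
    prl_records: dict[str, list[TrialRecordPRL]] = {}
    dg_records: dict[str, list[TrialRecordDG]] = {}
    children = task_ss.spawn(config.n_participants)
    for i, child in enumerate(children):
        pid = covariates["participant_id"].iloc[i]
        prl_p, social_p = _row_to_params(params.iloc[i])
        prl_rng, dg_rng = (np.random.default_rng(s) for s in child.spawn(2))
        prl_records[pid] = simulate_prl_agent(prl_env, prl_p, prl_rng)
        env = DGEnvironment(condition=covariates["condition"].iloc[i])
        dg_records[pid] = simulate_social_agent(env, social_p, dg_rng)
    return SyntheticCohort(config, covariates, true_params, prl_records, dg_records)
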