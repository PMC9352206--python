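"""Recovery analyses: parameter recovery, model recovery, and the
self-interest-sensitivity sweep.

Parameter recovery follows the generative protocol: fit the model to a
cohort, simulate fresh data from each participant's fitted estimates, refit,
and correlate generating with recovered values.  Model recovery simulates
agents from the winning belief-based model and asks how often an
information-criterion comparison puts a belief-based spec above every
associative spec.  The sweep simulates agents over a grid of self-interest
policy sensitivities (wSI) and measures how much each attribution stream
moves after the partner's policy reversal.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .associative import assoc_model_space
from .belief import (
    SocialBeliefParams,
    get_social_spec,
    simulate_social_agent,
    social_model_space,
    WINNING_SOCIAL_MODEL,
)
from .cohort import SyntheticCohort
from .fitting import FitConfig, fit_model
from .rl import PRLParams, get_prl_spec, simulate_prl_agent, WINNING_PRL_MODEL
from .stats import permutation_spearman
from .tasks import DGEnvironment, PRLEnvironment

#: Base parameterisation of the sensitivity sweep: symmetric mid-scale
#: priors sharpened by u = 2, moderate policy uncertainty, intercept -1,
#: shallow harmful-intent sensitivity, half-carryover reset.
SWEEP_BASE = dict(
    p_hi0=0.5, u_hi0=2.0, p_si0=0.5, u_si0=2.0, u_pi=2.0,
    w0=-1.0, w_hi=0.1, eta_dg=0.5,
)


def prl_params_from_row(row) -> PRLParams:
    return PRLParams(tau=row["tau"], lam1=row["lam1"], s=row["s"],
                     phi=row["phi"], eta_pr=row["eta_pr"])


def social_params_from_row(row) -> SocialBeliefParams:
    return SocialBeliefParams(
        p_hi0=row["p_hi0"], u_hi0=row["u_hi0"], p_si0=row["p_si0"],
        u_si0=row["u_si0"], u_pi=row["u_pi"], w0=row["w0"],
        w_hi=row["w_hi"], w_si=row["w_si"], eta_dg=row["eta_dg"],
    )


def parameter_recovery(
    prl_fits: pd.DataFrame,
    dg_fits: pd.DataFrame,
    conditions: dict[str, str],
    *,
    seed: int = 0,
    fit_config: Optional[FitConfig] = None,
) -> dict[str, pd.DataFrame]:
    """Generative parameter recovery from first-pass estimates.

    For every participant, simulate a fresh dataset per task from the fitted
    estimates and refit; returns per-parameter Pearson correlations between
    generating (fitted) and recovered values, plus the paired tables.
    """
    prl_spec = get_prl_spec(WINNING_PRL_MODEL)
    social_spec = get_social_spec(WINNING_SOCIAL_MODEL)
    penv = PRLEnvironment()
    ss = np.random.SeedSequence(seed)
    rows_p, rows_s = [], []
    n = len(prl_fits)
    for i, child in enumerate(ss.spawn(n)):
        s1, s2, s3, s4 = (
            int(c.generate_state(1)[0] % 2**31) for c in child.spawn(4)
        )
        rp = prl_fits.iloc[i]
        data = simulate_prl_agent(penv, prl_params_from_row(rp), s1)
        rows_p.append(
            fit_model(data, prl_spec, participant_id=rp["participant_id"],
                      seed=s2, config=fit_config).to_row()
        )
        rs = dg_fits.iloc[i]
        env = DGEnvironment(condition=conditions[rs["participant_id"]])
        data = simulate_social_agent(env, social_params_from_row(rs), s3)
        rows_s.append(
            fit_model(data, social_spec, participant_id=rs["participant_id"],
                      seed=s4, config=fit_config).to_row()
        )
    rec_p, rec_s = pd.DataFrame(rows_p), pd.DataFrame(rows_s)

    def corr_table(gen: pd.DataFrame, rec: pd.DataFrame, names: Sequence[str]):
        merged = gen.merge(rec, on="participant_id", suffixes=("_gen", "_rec"))
        return pd.DataFrame(
            {"parameter": list(names),
             "pearson_r": [
                 float(np.corrcoef(merged[f"{p}_gen"], merged[f"{p}_rec"])[0, 1])
                 for p in names
             ],
             "n": len(merged)}
        )

    return {
        "prl_recovered": rec_p,
        "dg_recovered": rec_s,
        "prl_correlations": corr_table(
            prl_fits, rec_p, ["tau", "lam1", "s", "phi", "eta_pr"]
        ),
        "dg_correlations": corr_table(
            dg_fits, rec_s,
            ["p_hi0", "u_hi0", "p_si0", "u_si0", "u_pi",
             "w0", "w_hi", "w_si", "eta_dg"],
        ),
    }


def model_recovery(
    n_agents: int = 100,
    *,
    seed: int = 0,
    w_si: float = 0.3,
    fit_config: Optional[FitConfig] = None,
) -> pd.DataFrame:
    """How often belief-generated data is best explained by a belief spec.

    Agents are simulated from the winning belief model at the sweep base
    parameters (wSI as given), alternating partner conditions.  Each agent
    is fitted with all six belief-based specs and all seven associative
    specs (bin-mass likelihood, so BICs are commensurable); the row records
    the best BIC in each family.
    """
    params = SocialBeliefParams(w_si=w_si, **SWEEP_BASE)
    bspecs = social_model_space()
    aspecs = assoc_model_space(bin_likelihood=True)
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(ss.spawn(n_agents)):
        seeds = [int(c.generate_state(1)[0] % 2**31) for c in child.spawn(14)]
        env = DGEnvironment(
            condition="initially_unfair" if i % 2 == 0 else "initially_fair"
        )
        data = simulate_social_agent(env, params, seeds[0])
        bfits = [
            fit_model(data, sp, participant_id=str(i), seed=seeds[1 + j],
                      config=fit_config)
            for j, sp in enumerate(bspecs)
        ]
        afits = [
            fit_model(data, sp, participant_id=str(i), seed=seeds[7 + j],
                      config=fit_config)
            for j, sp in enumerate(aspecs)
        ]
        best_b = min(bfits, key=lambda f: f.bic)
        best_a = min(afits, key=lambda f: f.bic)
        rows.append(
            {"agent": i, "condition": env.condition,
             "best_belief_model": best_b.model_id, "best_belief_bic": best_b.bic,
             "best_assoc_model": best_a.model_id, "best_assoc_bic": best_a.bic,
             "belief_wins": best_b.bic < best_a.bic}
        )
    return pd.DataFrame(rows)


def wsi_sweep(
    w_si_values: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    n_agents: int = 100,
    *,
    seed: int = 0,
    condition: str = "initially_unfair",
) -> pd.DataFrame:
    """Post-reversal attributional flexibility as a function of wSI.

    Flexibility of a stream is |mean rating trials 11-20 minus mean rating
    trials 1-10|, averaged over agents.  One row per wSI value.
    """
    env = DGEnvironment(condition=condition)
    ss = np.random.SeedSequence(seed)
    rows = []
    for w, child in zip(w_si_values, ss.spawn(len(w_si_values))):
        params = SocialBeliefParams(w_si=float(w), **SWEEP_BASE)
        d_si, d_hi = [], []
        for agent_ss in child.spawn(n_agents):
            recs = simulate_social_agent(
                env, params, np.random.default_rng(agent_ss)
            )
            hi = np.array([r.hi_rating for r in recs])
            si = np.array([r.si_rating for r in recs])
            cut = env.reversal_trial
            d_si.append(abs(si[cut:].mean() - si[:cut].mean()))
            d_hi.append(abs(hi[cut:].mean() - hi[:cut].mean()))
        rows.append(
            {"w_si": float(w), "si_flexibility": float(np.mean(d_si)),
             "hi_flexibility": float(np.mean(d_hi)), "n_agents": n_agents}
        )
    return pd.DataFrame(rows)


def permutation_type_i_rate(
    n_replicates: int = 200,
    n: int = 500,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    *,
    seed: int = 0,
) -> float:
    """Observed rejection rate of the permutation test on independent draws."""
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_replicates):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = permutation_spearman(
            x, y, n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        hits += res.p_value < alpha
    return hits / n_replicates
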