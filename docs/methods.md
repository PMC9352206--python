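# Methods

`socialrl` implements two families of trial-level computational models of
behaviour under covert contingency reversals — one non-social (a three-option
probabilistic reversal-learning task) and one social (a repeated-reversal
Dictator game with harmful-intent and self-interest attribution ratings) —
together with the machinery to fit them to individual participants, compare
them, and probe how well their parameters and structure can be recovered
from data of the size such studies actually collect.

## The reversal-learning family

The task presents three options over 60 trials; one pays +10 points with
probability 0.8, one with 0.5, one with 0.2 (−5 otherwise).  After trial 30
the contingencies rotate covertly (low→high, high→even, even→low).

All models are Q-learning variants with a softmax response.  Q values start
at 2.5 — the expected value of an option paying +10 or −5 at even odds — and
stay on the raw points scale, because two of the mechanisms below anchor on
that 2.5 mean.  Within a trial the order of operations is fixed: emit choice
probabilities from the current values, observe the outcome, update salience,
update the chosen option, decay the unchosen options.

- **Delta rule**: `Q ← Q + λ(r − Q)` for the chosen option; an optional
  second rate λ₂ replaces λ from trial 31 onward.
- **Pearce-Hall salience** (weight `S ∈ [0,1]`): a running average of
  absolute prediction-error magnitude,
  `salience ← S·|PE|/15 + (1−S)·salience`, gates the effective learning rate
  (`salience·λ`).  |PE| is divided by 15 — the largest attainable error given
  rewards in [−5, +10] and values bounded by the same interval — so salience
  stays in [0, 1] and λ keeps its usual interpretation.  Salience starts at
  1, which makes `S = 0` nest the plain delta-rule model exactly.
- **Memory decay** (retention `φ`): unchosen options drift toward the mean,
  `Q ← 2.5 − φ(2.5 − Q)`.
- **Reset-at-reversal** (`η_pr`): once, between trials 30 and 31, all values
  are pulled toward the mean, `Q ← Q + η_pr(2.5 − Q)`, modelling the
  expectation that "something changed at half-time".
- **Lapse** (`ζ`): the softmax policy is mixed with a uniform choice,
  `π = ζ/3 + (1−ζ)p`.

The registry holds eight specs, from a win-stay/lose-switch limit (τ = 0.01,
λ = 0.99, nothing fitted) up to the six-parameter full chain.  The
five-parameter salience + reset + decay model (`ph_reset_phi`) is the
family's reference ("winning") model.  The exact membership of the space is
a reconstruction; custom specs can be built from any parameter subset.

Likelihoods are evaluated in log space so that near-deterministic
parameterisations (τ → 0) stay finite.

## The belief-based social family

The participant watches a partner either split 10 points (return r = 0.5)
or keep them (r = 0) for 20 trials; the partner's 80/20 fair-or-unfair
policy reverses covertly after trial 10.  After each return the participant
rates the partner's harmful intent (HI) and self-interest (SI) on 0–100
scales.

The model maintains a joint probability grid over HI × SI, each discretised
into 9 bins (bin 1 "totally altruistic" … bin 9 "totally antisocial"):

- **Priors**: each marginal is `Binomial(8, p)^u`, renormalised — `p` sets
  the central tendency, `u` sharpens (>1) or blunts (<1) it; `u = 0` is
  uniform.  The joint prior is the product of marginals (independence is
  assumed only at t = 0; updates induce correlation).
- **Policy map**: the assumed probability of an unfair return is
  `σ(w₀ + w_HI(HI−5) + w_SI(SI−5))` per cell — an intercept plus
  sensitivities to each attribute, centred on the middle bin.
- **Update**: exact Bayes on the 81 cells after each observed return.
- **Emission**: the reported rating pair is scored against a blunted copy of
  the posterior, `p̂ ∝ p^(1/uπ) + ξ`, with policy uncertainty `uπ` and a
  small fixed lapse `ξ = 0.02/81` (never fitted).  Ratings map to bins by
  equal-width binning; simulation emits bin centres.  The likelihood of a
  trial is the single joint cell probability — the model text gives no
  continuous response kernel, so the bin-cell mass is the minimal reading.
- **Propagation**: the *unblunted* posterior carries to the next trial; the
  formalism is ambiguous on whether the blunted distribution should
  propagate instead, so this is a switch (`propagate_blunted`, default
  off).
- **Reset** (`η_dg`): between trials 10 and 11 the block-2 prior is the
  convex mixture `(1−η)·prior₀ + η·posterior₁₀`.  A two-weight variant
  mixes the HI and SI marginals separately and rebuilds the joint as their
  product (the algebra of that variant is a reconstruction).

Six specs: {fixed, free policy map} × {0, 1, 2 reset weights}.  The
fixed-map constants default to w₀ = −1, w_HI = w_SI = 0.1, near
population-typical estimates; the free-map one-η spec (`bb_free_1eta`,
9 parameters) is the reference model.

## The associative comparator family

A deliberately leaner account: a single cached "expected social value"
(ESV ∈ [0, 0.5], the return scale) follows the returns by a delta rule with
rate α, and each attribution is predicted as a logistic function of the
centred latent (`σ(intercept + slope·(esv − 0.25))`), with Gaussian rating
noise σ shared across both attributions.  Variants: {shared, separate}
attribution mappings × {0, 1, 2} reset weights on the latent, plus a
dual-learning-rate member — seven specs.  Every member learns (a frozen
latent would contradict the family's defining delta rule).

Two likelihood conventions exist: the natural Gaussian *density* of
rating/100 (used within-family), and a truncated-Gaussian *bin mass* on the
same 9-bin grid the belief models emit over.  Information-criterion
comparison across families uses the bin-mass form only: a density over 40
continuous observations and a mass over 20 discrete pairs are not on a
common measure, and comparing them directly would favour the associative
family by roughly `40·ln 9` nats of pure unit mismatch.

## Fitting and model comparison

Per-participant MAP estimation maximises the log-likelihood plus weak,
range-restricting priors: Beta(1.2, 1.2) on unit-interval parameters,
Gamma(shape 2, scale 3) on positive ones (τ, the u exponents, σ),
Normal(0, 5) on intercepts/slopes and half-normal(5) on the non-negative
policy sensitivities.  All parameters live in finite boxes and are optimised
through a scaled-logit transform.

The pipeline is staged: a Latin-hypercube scan of the box (200 points),
short simulated-annealing chains from the three best scan points (120
Gaussian proposals each, geometric temperature 1 → 0.01), then a
Nelder-Mead polish followed by L-BFGS-B.  The budget was chosen as the
smallest at which doubling every stage left the optima unchanged on both
winning models; everything is deterministic under a fixed seed.
`FitConfig.fast()` is a reduced budget for smoke tests.

BIC = −2LL + k·ln n and AIC = −2LL + 2k with n = one observation per trial
(60 / 20; a Dictator-game trial contributes one joint rating-pair
observation).  Ties in comparison tables break toward fewer parameters,
then lexicographic model id.

## Synthetic cohorts

No participant data ship with the package; a generator produces cohorts
with the study population's covariate structure:

- **Paranoia** (persecutory-ideation score): negative binomial clipped at
  33, with the underlying mean and dispersion solved numerically so the
  *clipped* draw matches mean 3.88 and sd 6.18 — integer, ~1/3 zeros,
  strongly right-tailed.
- **ICAR** (fluid intelligence): normal truncated to [0, 11] with the
  location solved so the truncated mean is 4.96 (scale 2.42).

Generating parameters for both winning models are drawn on link scales
(log for positive, logit for unit-interval parameters) as
`link = μ + σ_link(s·z + √(1−s²)ε)` with z the population-standardised
paranoia, so the link-scale correlation equals the standardised slope `s`.
Default slopes couple paranoia to τ (0.13), pHI₀ (0.16), uπ (0.17) and
w_SI (0.15); all other parameters are uncoupled.  The base spreads cover
the psychologically plausible range of each parameter (e.g. w_SI spanning
roughly 0.1–0.9, the range over which simulated attributional flexibility
visibly varies; reset weights near-uniform), so cohorts double as
recovery-study populations.  Condition assignment (initially fair/unfair
partner) alternates deterministically.

What the generator does *not* emulate: questionnaire item structure,
dropout, age/sex covariates, response times, within-participant rating
anchoring, or any true causal path from paranoia to parameters — the slopes
are descriptive stand-ins with the sign and magnitude of fitted regression
coefficients.  Passing tests therefore show that the pipeline recovers
structure *built into* data of this size and noise level, not that the real
population has that structure.

## Recovery analyses

**Parameter recovery** follows the generative protocol: fit the cohort,
simulate one fresh dataset per participant from the fitted estimates, refit,
and correlate generating with recovered values.  With 60 choice trials and
20 rating trials, the well-identified parameters (τ, λ, pHI₀, pSI₀, policy
weights) recover strongly; the reset weights are intrinsically hard — a
single covert reversal provides effectively one observation of each — and
their recovery correlations sit in the 0.3–0.5 range at these trial counts
regardless of optimiser effort (split-half reliability of the MAP estimates
bounds them).  This limitation is a property of the task design, and is
reported rather than hidden.

**Model recovery** simulates agents from the winning belief model
(symmetric mid-scale priors sharpened by u = 2, uπ = 2, w₀ = −1,
w_HI = 0.1, w_SI = 0.3, η = 0.5, alternating conditions) and fits all six
belief specs and all seven associative specs (bin-mass likelihood); the
question is how often the best belief BIC beats the best associative BIC.

**Sensitivity sweep**: holding the base parameters fixed and sweeping
w_SI over 0.1…0.9 (100 agents per value), post-reversal flexibility —
|mean rating after reversal − mean rating before| — rises monotonically for
self-interest but not for harmful intent, the model's signature asymmetry.

## Statistics

Win-switch rate: among rewarded trials with a successor in scope, the
fraction followed by a different choice; lose-stay analogous.  The
trial-30→31 transition belongs to the pre-reversal scope (its feedback
arrived pre-reversal).  Zero denominators yield missing values, never 0.
Permutation Spearman correlations shuffle one variable B times; the p-value
is two-sided with add-one correction, `p = (1 + #{|ρ*| ≥ |ρ|})/(B + 1)`,
hence never zero and invariant to monotone transforms.

## Numerical choices and degenerate inputs

Binomial-power priors are computed in log space (exponent-zero and
endpoint-p cases special-cased); softmax likelihoods in log space; the
emission lapse ξ floors every cell so no observed rating has zero mass; grid
normalisation is enforced to 1e−10 in tests.  Gaussian bin masses are
floored at 1e−300 before the log.  Fit failures (non-finite posterior
everywhere) return a result flagged `converged = False` rather than raising.

## Known limitations

- Reset-weight recovery is ceiling-limited by the single-reversal design
  (above).
- With the population effect sizes used as defaults (standardised slopes
  0.13–0.17), cross-participant paranoia–parameter correlations at desk-
  scale n are underpowered for conventional significance; detecting all
  four simultaneously requires cohorts near the original study's size even
  with perfect recovery.
- The associative family and the two-η belief variant are reconstructions
  from a prose description; their structural choices are config-visible.
- The 8-spec reversal-learning registry is a defensible reconstruction of
  the published family, not a verbatim copy.
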