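# Methods

## Structural models

Both simulation scenarios share a two-period causal skeleton on binary
variables: an exogenous confounder X₁ ~ Bernoulli(0.5) that the default
analyses treat as unmeasured, treatments T₁ and T₂, an intermediate
confounder X₂ affected by T₁, and an outcome Y. Every conditional is a
Bernoulli with a logistic linear predictor.

Scenario A (perfect instruments):

```
logit P(T₁=1) = −10 + log(5)·X₁ + Σₛ αₛ·X₃Aₛ
logit P(X₂=1) = −1  + log(5)·T₁ + log(5)·X₁
logit P(T₂=1) = −10 + log(1.2)·T₁ + log(5)·X₁ + log(2)·X₂ + Σₛ γₛ·X₃Aₛ
logit P(Y=1)  = −1  + log(1.2)·T₁ + log(1.5)·T₂ + log(1.5)·T₁T₂
                    + log(5)·X₁ + log(2)·X₂
```

with X₃A₁..₉ iid N(0, 1) and (αₛ, γₛ) on the 3×3 grid of log odds ratios
{log 2, log 5, log 10}²: instrument s has α cycling 2/5/10 within blocks
of three and γ constant per block, so X₃A₃ is the strongest T₁-only
instrument, X₃A₇ the strongest T₂-only one, and X₃A₉ strongest on both.

Scenario B (one near-instrument) replaces the nine X₃A by
X₃B ~ N(β₁X₁, 1) with coefficient log(10) on both treatment equations,
and uses intercepts (−6, −1, −7, −0.5) and X₁ coefficients log 2 in the
X₂ and Y equations. Because X₃B's mean tracks X₁, its correlation with
the unmeasured confounder is 0.5β₁/√(1+0.25β₁²) ≈ β₁/2; the default sweep
is β₁ ∈ {0.01, 0.05, 0.1, 0.2, 0.3}.

The exclusion restriction is structural: the X₂ and Y linear predictors
are assembled from term lists (`X2_EQUATION_TERMS`, `Y_EQUATION_TERMS`)
that contain no instrument, so no parameter choice can leak an instrument
into the outcome side.

## Counterfactual truth

Because the instruments enter only treatment assignment, the true marginal
means need no instrument draws:

E[Y^{t₁,t₂}] = Σ_{x₁∈{0,1}} ½ Σ_{x₂∈{0,1}} P(X₂=x₂ | t₁, x₁) · expit(lp_Y(t₁,t₂,x₁,x₂)).

`closed_form_truth` evaluates this exactly (deterministic, O(1)); it is
the canonical truth in all bias computations. `generate_potential_outcomes`
keeps the brute-force route — simulate X₂^{t₁} and Y^{t₁,t₂} per subject —
as a cross-check, since a 10⁷-subject version of that simulation is what a
practitioner would run. Potential outcomes are drawn independently across
regimes: only marginal means enter the estimands, so no cross-world joint
distribution is implied or should be read off the table.

Known inconsistency: exact evaluation of the scenario-A equations gives
single-year truths of 8.32 and 7.99 percentage points but a both-years
truth of +22.97 pp. The source study reports 6.4 pp for the (1,1)
contrast and describes it as negative in its figures; that cannot be
reproduced from the printed equations under any reading we found, so the
(1,1) contrast is excluded from external-value checks and covered instead
by internal oracle equivalence (closed form vs 10⁷-draw simulation).

## Estimator

`fit_g_models` fits logistic regressions X₂ ~ T₁ + adj and
Y ~ T₁ + T₂ + T₁T₂ + X₂ + adj by maximum likelihood (statsmodels `Logit`).
The T₁×T₂ product is included by default — the data-generating process
contains it, and the study design isolates omitted-confounder bias rather
than functional-form misspecification — with `include_interaction=False`
available to quantify the additive reading. Non-convergence is recorded on
the returned object and propagated as a flag; a constant outcome or
regressor column raises `DegenerateDataError`.

`standardize` integrates the binary intermediate exactly (sum over
X₂ ∈ {0,1}) and averages over the empirical adjustment-covariate
distribution. This removes one layer of avoidable Monte Carlo noise
relative to the classic simulate-X₂-then-predict algorithm;
`standardize_mc` retains that stochastic backend, and the two are held to
agreement within Monte Carlo error by tests. Covariates enter on their raw
scales throughout.

## Simulation driver

`run_condition` generates replicate r with seed `base_seed + r`, so
conditions sharing a base seed are evaluated on identical datasets (paired
comparisons of adjustment sets, mirroring a fit-many-models-per-dataset
design) and results are independent of execution order; no parallel
backend is needed at desk scale (a full default grid takes about a
minute). Bias is reported as 100·(mean estimate − closed-form truth) and
spread as 100·SD across replicates, both in percentage points. Replicates
whose fits fail to converge are counted and kept (dropping them would
distort summaries invisibly); degenerate replicates are dropped and
reflected in `n_reps_used`. With a single replicate the SE fields are NaN.
The full study design uses 10,000 replicates and sample sizes 500 / 10,000
/ 200,000; the desk default is 500 replicates at N=10,000, where the
Monte Carlo SE of a bias estimate is roughly 0.1 pp — small against the
5.5 / 4.3 pp effects of interest.

## Case-study pipeline

`synthetic_case_study` emulates the structure of a physician-payments
cohort: measured baseline covariates (binary sex, years in practice,
case-mix score, a 4-level specialty code, baseline prescribing rate in
[0, 100]), a binary near-IV x3 (non-opioid payments), binary treatments in
two years, and continuous prescribing rates x2 and y. A latent
patient-severity factor U ~ N(0, 1) raises both x3 (log-odds scale) and y
(rate scale) with common strength `near_iv_confounding`; at 0 the
exclusion restriction holds exactly. Defaults were fixed once to look like
the real setting — treatment prevalence ~10%, x3 prevalence ~46%, outcome
rates with means near 5–8% — and give true contrasts d10=6.4, d01=3.5,
d11=10.9 pp (same order of magnitude as published payment–prescribing
estimates). Rates are clipped to [0, 100]; intercepts and noise scales
keep clipping below ~0.4% of rows so the no-clipping linear truth stored
as metadata is accurate to well under 0.1 pp. What a green test against
this generator does *not* establish: robustness to skewed, zero-inflated
real prescribing rates, to missing covariates, or to the 30-category
specialty structure of the real data.

`gcomp_case_study` runs the seven steps with OLS working models (fit via
statsmodels formulas, specialty entering as dummies). Treatment redraws
are marginal and independent across years, matching the algorithm's stated
intent; one redraw per subject by default, with `mc_multiplier` to shrink
assignment noise and an `"all_regimes"` backend that evaluates every
regime for every subject — deterministic given the fits and equal in
expectation, which tests verify. Predictions use conditional means without
residual noise (exact for linear models and marginal means). If a redrawn
treatment cell is empty (possible at small n) the assignment size is
increased tenfold and retried once; a still-empty cell yields a flagged
estimate. Confidence intervals are 2.5/97.5 percentiles over subject-level
nonparametric bootstrap resamples (default 200), with the point estimate
not guaranteed to lie inside a percentile interval.

## Numerical and RNG choices

- One `numpy` Generator per replicate, consumed in the fixed order
  X₁ → X₃ → T₁ → X₂ → T₂ → Y.
- Analysis-side randomness (treatment reassignment, Monte Carlo
  integration) runs on a *spawned child* of the user's seed. Reusing one
  integer for both data generation and analysis is a realistic habit, and
  with a shared PCG64 stream the redraws correlate with the cohort's own
  covariate and noise draws — we observed multi-sigma bias in the
  reassignment backend before decoupling the streams.
- Logistic fits use Newton iterations capped at 100; separation and
  singular designs are caught and flagged rather than raised.
- Standardized means are convex combinations of expits, hence always valid
  probabilities regardless of coefficient values.

## Limitations

- Two periods, binary treatments, logistic/linear links only.
- The bias-amplification magnitudes are specific to this data-generating
  process; the package makes the grid and coefficients configurable
  precisely so sensitivity to that choice can be explored.
- No variance estimation for the simulation-study estimator beyond
  empirical SEs across replicates; the bootstrap lives only in the
  case-study pipeline.
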