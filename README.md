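# gcompbias

Bias amplification in parametric g-computation for time-varying treatments.

## The problem

Epidemiologists estimating the joint effect of a treatment given at two
time points (say, a physician receiving industry payments in two
consecutive years, with their opioid prescribing rate as the outcome)
routinely use the g-formula: fit a model for the treatment-affected
intermediate confounder X₂, fit a model for the outcome Y, and standardize
the predictions over hypothetical treatment regimes. A perennial question
is which covariates belong in those working models. Adding a variable that
predicts treatment but affects the outcome *only through* treatment — an
instrumental variable (IV) — is known to amplify bias from unmeasured
confounding in point-treatment settings. This package quantifies the same
phenomenon for two-period g-computation, including the "near-IV" case
where the candidate covariate is also weakly correlated with the
unmeasured confounder and can therefore act as a proxy adjuster instead.

## What it implements

- **Data-generating processes** (`gcompbias.dgp`): binary treatments T₁,
  T₂, an unmeasured Bernoulli(0.5) confounder X₁, a binary time-varying
  confounder X₂ affected by T₁, and a binary outcome Y, all logistic.
  Scenario A adds nine perfect IVs X₃A₁..₉ (iid N(0,1)) on a 3×3 grid of
  treatment odds ratios {2, 5, 10}×{2, 5, 10}; scenario B adds one near-IV
  X₃B ~ N(β₁X₁, 1) with OR 10 on both treatments and a tunable confounder
  association β₁. True counterfactual contrasts
  E[Y^{t₁,t₂}] − E[Y^{0,0}] come in closed form by summation over (X₁, X₂)
  or from per-subject potential-outcome simulation.
- **Estimator** (`gcompbias.gcomputation`): logistic models
  X₂ ~ T₁ + adj and Y ~ T₁ + T₂ + T₁T₂ + X₂ + adj, standardized exactly
  over the binary X₂ (a Monte Carlo integration backend is kept for
  cross-checking).
- **Replication driver** (`gcompbias.simulation_study`): bias and
  empirical SE, in percentage points, over replicate grids of sample size,
  adjustment set and β₁.
- **Case-study pipeline** (`gcompbias.case_study`): the seven-step linear
  g-computation algorithm (two OLS fits, marginal random treatment
  reassignment, cell-mean contrasts, 200-resample percentile bootstrap)
  run on a synthetic physician-payments-style cohort with a latent
  patient-severity confounder behind its near-IV.

## Worked example

```bash
$ gcompbias truth --scenario A
E[Y^(1,0)] - E[Y^(0,0)] =   8.3177 pp
E[Y^(0,1)] - E[Y^(0,0)] =   7.9932 pp
E[Y^(1,1)] - E[Y^(0,0)] =  22.9674 pp
```

These are the true effects, in percentage points of outcome risk, of
treatment in year 1 only, year 2 only, and both years. Now estimate them
while *omitting* the unmeasured confounder, with and without the strongest
T₁ instrument in the working models:

```python
from gcompbias import (AdjustmentSet, DGPConfigA, run_condition)

cfg = DGPConfigA()
for adj in (AdjustmentSet(), AdjustmentSet(("x3_3",))):
    s = run_condition(cfg, n=10_000, adj=adj, n_reps=500, base_seed=20220425)
    print(f"{adj.label:>6}: bias(1,0) = {s.bias_10:5.2f} pp, "
          f"bias(0,1) = {s.bias_01:5.2f} pp")
```

```
  none: bias(1,0) =  5.51 pp, bias(0,1) =  4.41 pp
  x3_3: bias(1,0) =  5.76 pp, bias(0,1) =  4.41 pp
```

Omitting X₁ alone already biases the single-year effects upward by ~5.5
and ~4.4 points; additionally adjusting for an IV that strongly predicts
T₁ pushes the (1,0) bias further from zero while leaving (0,1) nearly
unchanged — bias amplification targeted at the treatment the instrument
predicts. The `simulate` and `case-study` subcommands write these
summaries as tidy CSVs with a run manifest.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the two single-year true contrasts from a
10,000,000-subject potential-outcome simulation; the unadjusted
estimator's Monte Carlo bias for both contrasts over 500 replicates of
N=10,000; and the smallest β₁ in {0.01, 0.05, 0.1, 0.2, 0.3} at which
near-IV adjustment reduces (rather than amplifies) absolute bias for all
three contrasts. Results land in the JSON file given by `--out`.
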