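"""Monte Carlo replication driver: bias and empirical SE across conditions.

A *condition* is one combination of scenario, sample size, adjustment set
and (scenario B) confounder-association strength beta1.  For each condition
the driver generates ``n_reps`` independent datasets, runs the g-computation
estimator on each, and summarizes

    bias = 100 * (mean estimate - closed-form truth)      [percentage points]
    SE   = 100 * SD of estimates across replicates        [percentage points]

Replicate r always uses seed ``base_seed + r``, so conditions sharing a
``base_seed`` are evaluated on identical datasets (paired comparisons of
adjustment sets, as in a fit-several-models-per-dataset design) and results
do not depend on execution order or parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from gcompbias.dgp import (
    DEFAULT_BETA1_GRID,
    DGPConfig,
    DGPConfigA,
    DGPConfigB,
    closed_form_truth,
    generate_scenario_a,
    generate_scenario_b,
)
from gcompbias.gcomputation import (
    AdjustmentSet,
    DegenerateDataError,
    fit_g_models,
    standardize,
)

__all__ = [
    "StudyGrid",
    "SimulationSummary",
    "run_condition",
    "run_grid",
    "default_adjustment_conditions",
]

#: Sample sizes of the full study design.
DEFAULT_SAMPLE_SIZES = (500, 10_000, 200_000)


def default_adjustment_conditions(scenario: str) -> tuple:
    """Unadjusted plus each single-instrument adjustment for a scenario."""
    if scenario == "A":
        return (AdjustmentSet(),) + tuple(
            AdjustmentSet((f"x3_{s}",)) for s in range(1, 10)
        )
    if scenario == "B":
        return (AdjustmentSet(), AdjustmentSet(("x3b",)))
    raise ValueError(f"scenario must be 'A' or 'B', got {scenario!r}")


@dataclass(frozen=True)
class StudyGrid:
    """Full factorial design of a simulation experiment."""

    scenario: str = "A"
    sample_sizes: tuple = (10_000,)
    n_reps: int = 500
    adjustment_conditions: tuple = None
    beta1_values: tuple = DEFAULT_BETA1_GRID
    base_seed: int = 20_220_425

    def __post_init__(self):
        if self.scenario not in ("A", "B"):
            raise ValueError(f"scenario must be 'A' or 'B', got {self.scenario!r}")
        if self.adjustment_conditions is None:
            object.__setattr__(
                self,
                "adjustment_conditions",
                default_adjustment_conditions(self.scenario),
            )
        object.__setattr__(self, "sample_sizes", tuple(self.sample_sizes))
        object.__setattr__(self, "beta1_values", tuple(self.beta1_values))
        if int(self.n_reps) < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not self.sample_sizes or any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if not self.adjustment_conditions:
            raise ValueError("at least one adjustment condition required")


@dataclass(frozen=True)
class SimulationSummary:
    """Bias / empirical-SE summary for one condition (percentage points).

    ``se_*`` is NaN when only one replicate was run.  Replicates whose fits
    did not converge are counted in ``n_nonconverged`` but kept in the
    summaries; degenerate replicates (a constant model column, possible at
    n=500) are dropped and reflected in ``n_reps_used``.
    """

    scenario: str
    n: int
    adjustment: str
    beta1: float | None
    bias_10: float
    bias_01: float
    bias_11: float
    se_10: float
    se_01: float
    se_11: float
    mean_10: float
    mean_01: float
    mean_11: float
    truth_10: float
    truth_01: float
    truth_11: float
    n_nonconverged: int
    n_reps_used: int

    def bias(self, contrast: str) -> float:
        return getattr(self, f"bias_{contrast}")


def _base_config(scenario: str, beta1: float | None = None) -> DGPConfig:
    if scenario == "A":
        return DGPConfigA()
    cfg = DGPConfigB()
    return cfg if beta1 is None else replace(cfg, beta1=beta1)


def run_condition(
    config: DGPConfig,
    n: int,
    adj: AdjustmentSet,
    n_reps: int,
    base_seed: int,
    include_interaction: bool = True,
) -> SimulationSummary:
    """Simulate one condition and summarize bias and empirical SE."""
    if int(n_reps) < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if int(n) < 1:
        raise ValueError(f"n must be positive, got {n}")
    gen = generate_scenario_a if isinstance(config, DGPConfigA) else generate_scenario_b
    truth = closed_form_truth(config)
    estimates = []
    n_nonconverged = 0
    for r in range(1, int(n_reps) + 1):
        data = gen(config.replace(n=int(n), seed=base_seed + r))
        try:
            models = fit_g_models(data, adj, include_interaction=include_interaction)
        except DegenerateDataError:
            continue
        est = standardize(models, data)
        if not est.converged:
            n_nonconverged += 1
        estimates.append(est.as_tuple())
    est = np.asarray(estimates, dtype=float)
    mean = est.mean(axis=0)
    sd = est.std(axis=0, ddof=1) if len(est) > 1 else np.full(3, np.nan)
    t = np.asarray(truth.as_tuple())
    scenario = "A" if isinstance(config, DGPConfigA) else "B"
    return SimulationSummary(
        scenario=scenario,
        n=int(n),
        adjustment=adj.label,
        beta1=(config.beta1 if isinstance(config, DGPConfigB) else None),
        bias_10=100.0 * (mean[0] - t[0]),
        bias_01=100.0 * (mean[1] - t[1]),
        bias_11=100.0 * (mean[2] - t[2]),
        se_10=100.0 * sd[0],
        se_01=100.0 * sd[1],
        se_11=100.0 * sd[2],
        mean_10=mean[0],
        mean_01=mean[1],
        mean_11=mean[2],
        truth_10=t[0],
        truth_01=t[1],
        truth_11=t[2],
        n_nonconverged=n_nonconverged,
        n_reps_used=len(est),
    )


def run_grid(grid: StudyGrid) -> list:
    """Run every condition of a :class:`StudyGrid`.

    Scenario A iterates sample sizes x adjustment conditions; scenario B
    additionally iterates the beta1 grid.  The unadjusted condition is part
    of the default conditions so that bias *increase* (adjusted minus
    unadjusted) is always computable from the output.
    """
    summaries = []
    beta1_values = grid.beta1_values if grid.scenario == "B" else (None,)
    for beta1 in beta1_values:
        config = _base_config(grid.scenario, beta1)
        for n in grid.sample_sizes:
            for adj in grid.adjustment_conditions:
                summaries.append(
                    run_condition(config, n, adj, grid.n_reps, grid.base_seed)
                )
    return summaries
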