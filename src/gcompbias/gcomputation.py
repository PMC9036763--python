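"""Two-period parametric g-computation for binary outcomes.

The estimator fits two working logistic regressions:

1. the intermediate model  ``X2 ~ T1 + adjustment covariates``
2. the outcome model       ``Y ~ T1 + T2 + T1:T2 + X2 + adjustment covariates``

and standardizes: for each regime (t1, t2) the counterfactual mean is the
empirical average, over subjects' adjustment-covariate values, of the
outcome-model prediction integrated over the binary intermediate,

    E_hat[Y^{t1,t2}] = (1/n) sum_i sum_{x2 in {0,1}}
        P_hat(X2 = x2 | t1, adj_i) * P_hat(Y = 1 | t1, t2, x2, adj_i).

The exact summation over X2 replaces the simulate-then-predict Monte Carlo
step of the classic algorithm; :func:`standardize_mc` keeps that stochastic
backend for cross-checking.  The unmeasured confounder X1 is adjustable like
any other column, which is how correct-specification checks are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from gcompbias.dgp import REGIMES, TrialDataset

__all__ = [
    "AdjustmentSet",
    "FittedGModels",
    "ContrastEstimate",
    "DegenerateDataError",
    "fit_g_models",
    "standardize",
    "standardize_mc",
]


class DegenerateDataError(ValueError):
    """A model column is constant (no information to fit on)."""


@dataclass(frozen=True)
class AdjustmentSet:
    """Extra covariates entering both working models.

    The treatments and X2 are always in the models and never listed here.
    The empty set is the paper-style unadjusted analysis; a single
    instrument column probes bias amplification; ``("x1",)`` is the
    correctly specified benchmark.
    """

    covariates: tuple = ()

    def __post_init__(self):
        names = tuple(self.covariates)
        object.__setattr__(self, "covariates", names)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate adjustment covariates in {names}")
        reserved = {"t1", "t2", "x2", "y"}
        bad = reserved.intersection(names)
        if bad:
            raise ValueError(
                f"{sorted(bad)} are always in the models; do not list them"
            )

    @property
    def label(self) -> str:
        return "+".join(self.covariates) if self.covariates else "none"


@dataclass(frozen=True)
class FittedGModels:
    """Coefficients of the two fitted working models.

    Parameter vectors are ordered ``(const, t1, *adj)`` for the X2 model and
    ``(const, t1, t2, [t1:t2,] x2, *adj)`` for the Y model.
    """

    x2_params: np.ndarray
    y_params: np.ndarray
    x2_converged: bool
    y_converged: bool
    n_used: int
    adjustment: AdjustmentSet
    include_interaction: bool = True

    @property
    def converged(self) -> bool:
        return bool(self.x2_converged and self.y_converged)


@dataclass(frozen=True)
class ContrastEstimate:
    """Estimated counterfactual means and contrasts against (0, 0)."""

    d10: float
    d01: float
    d11: float
    ey: dict = field(default_factory=dict)
    converged: bool = True

    def as_tuple(self) -> tuple:
        return (self.d10, self.d01, self.d11)


def _adj_matrix(data: TrialDataset, adj: AdjustmentSet) -> np.ndarray:
    cols = []
    for name in adj.covariates:
        try:
            cols.append(np.asarray(data.column(name), dtype=float))
        except KeyError:
            raise ValueError(
                f"adjustment covariate {name!r} not found in dataset "
                f"(available: x1, {', '.join(data.x3_names)})"
            ) from None
    if not cols:
        return np.empty((data.n, 0))
    return np.column_stack(cols)


def _fit_logit(endog, exog, colnames):
    for j, name in enumerate(colnames):
        if np.ptp(exog[:, j]) == 0 and name != "const":
            raise DegenerateDataError(f"column {name!r} is constant")
    if np.ptp(endog) == 0:
        raise DegenerateDataError("outcome column is constant")
    try:
        res = sm.Logit(endog, exog).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)):
            converged = False
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        params = np.full(exog.shape[1], np.nan)
        converged = False
    return params, converged


def fit_g_models(
    data: TrialDataset,
    adj: AdjustmentSet = AdjustmentSet(),
    include_interaction: bool = True,
) -> FittedGModels:
    """Fit the two working logistic models by maximum likelihood.

    Non-convergence (expected occasionally at small n) is recorded on the
    returned object, not raised; a constant outcome or regressor column
    raises :class:`DegenerateDataError`.
    """
    n = data.n
    t1 = np.asarray(data.t1, dtype=float)
    t2 = np.asarray(data.t2, dtype=float)
    x2 = np.asarray(data.x2, dtype=float)
    y = np.asarray(data.y, dtype=float)
    adjmat = _adj_matrix(data, adj)

    n_params_y = 4 + include_interaction + adjmat.shape[1]
    if n < n_params_y + 1:
        raise ValueError(f"n={n} too small for {n_params_y} parameters")

    const = np.ones(n)
    x2_exog = np.column_stack([const, t1, adjmat])
    x2_names = ["const", "t1", *adj.covariates]
    y_cols = [const, t1, t2]
    y_names = ["const", "t1", "t2"]
    if include_interaction:
        y_cols.append(t1 * t2)
        y_names.append("t1:t2")
    y_cols.append(x2)
    y_names.append("x2")
    y_exog = np.column_stack([*y_cols, adjmat])
    y_names += list(adj.covariates)

    x2_params, x2_conv = _fit_logit(x2, x2_exog, x2_names)
    y_params, y_conv = _fit_logit(y, y_exog, y_names)
    return FittedGModels(
        x2_params=x2_params,
        y_params=y_params,
        x2_converged=x2_conv,
        y_converged=y_conv,
        n_used=n,
        adjustment=adj,
        include_interaction=include_interaction,
    )


def _regime_probs(models: FittedGModels, adjmat: np.ndarray, t1: int, t2: int):
    """P_hat(X2=1|t1, adj_i) and P_hat(Y=1|t1, t2, x2, adj_i) for x2=0,1."""
    bx = models.x2_params
    by = models.y_params
    adj_x2 = adjmat @ bx[2:] if adjmat.shape[1] else 0.0
    p_x2 = expit(bx[0] + bx[1] * t1 + adj_x2)
    k = 4 if models.include_interaction else 3
    lp = by[0] + by[1] * t1 + by[2] * t2
    if models.include_interaction:
        lp = lp + by[3] * t1 * t2
    adj_y = adjmat @ by[k + 1:] if adjmat.shape[1] else 0.0
    p_y0 = expit(lp + adj_y)
    p_y1 = expit(lp + by[k] + adj_y)
    return p_x2, p_y0, p_y1


def standardize(
    models: FittedGModels,
    data: TrialDataset,
    adj: AdjustmentSet | None = None,
) -> ContrastEstimate:
    """Standardize fitted models to counterfactual means, exactly in X2.

    The binary intermediate is integrated by direct summation over {0, 1};
    adjustment covariates are averaged empirically over the sample.
    """
    adj = models.adjustment if adj is None else adj
    adjmat = _adj_matrix(data, adj)
    ey = {}
    for t1, t2 in REGIMES:
        p_x2, p_y0, p_y1 = _regime_probs(models, adjmat, t1, t2)
        ey[(t1, t2)] = float(np.mean((1.0 - p_x2) * p_y0 + p_x2 * p_y1))
    e00 = ey[(0, 0)]
    return ContrastEstimate(
        d10=ey[(1, 0)] - e00,
        d01=ey[(0, 1)] - e00,
        d11=ey[(1, 1)] - e00,
        ey={f"ey_{a}{b}": v for (a, b), v in ey.items()},
        converged=models.converged,
    )


def standardize_mc(
    models: FittedGModels,
    data: TrialDataset,
    n_draws: int = 100_000,
    seed: int = 0,
    adj: AdjustmentSet | None = None,
) -> ContrastEstimate:
    """Monte Carlo standardization backend: simulate X2 ~ Bernoulli(P_hat).

    Kept as the classic simulate-then-predict algorithm; agrees with
    :func:`standardize` up to Monte Carlo error.  ``n_draws`` is the total
    number of simulated subject-draws per regime (the sample is recycled
    ceil(n_draws / n) times).
    """
    adj = models.adjustment if adj is None else adj
    adjmat = _adj_matrix(data, adj)
    n = data.n
    passes = max(1, int(np.ceil(n_draws / n)))
    # child stream: immune to seed reuse between generation and integration
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    ey = {}
    for t1, t2 in REGIMES:
        p_x2, p_y0, p_y1 = _regime_probs(models, adjmat, t1, t2)
        total = 0.0
        for _ in range(passes):
            x2_sim = rng.random(n) < p_x2
            total += float(np.mean(np.where(x2_sim, p_y1, p_y0)))
        ey[(t1, t2)] = total / passes
    e00 = ey[(0, 0)]
    return ContrastEstimate(
        d10=ey[(1, 0)] - e00,
        d01=ey[(0, 1)] - e00,
        d11=ey[(1, 1)] - e00,
        ey={f"ey_{a}{b}": v for (a, b), v in ey.items()},
        converged=models.converged,
    )
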