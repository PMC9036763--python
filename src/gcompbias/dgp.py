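"""Data-generating processes for the two-period bias-amplification study.

Two scenarios share the same causal skeleton: a baseline confounder X1
(Bernoulli(0.5), treated as *unmeasured* by the default analyses), binary
treatments T1 and T2, a binary time-varying confounder X2 affected by T1,
and a binary outcome Y. They differ in the treatment-only covariates:

* **Scenario A** adds nine perfect instruments X3A_1..X3A_9, iid standard
  normal, entering only the T1 and T2 equations with log-odds strengths
  taken from a 3x3 grid (OR 2 / 5 / 10 on each treatment).
* **Scenario B** adds a single near-instrument X3B ~ Normal(beta1 * X1, 1):
  strongly associated with both treatments (OR 10 per unit) and correlated
  with the unmeasured confounder through its mean, so it is a proxy
  confounder rather than a perfect IV.

All structural equations are logistic.  The instruments never enter the X2
or Y equations, which is what makes them (near-)IVs; that exclusion is
structural here — see :data:`X2_EQUATION_TERMS` and :data:`Y_EQUATION_TERMS`.

Counterfactual truth is available two ways: exactly, by summing the outcome
equation over the four (X1, X2) cells (:func:`closed_form_truth`), or by
simulating per-subject potential outcomes (:func:`generate_potential_outcomes`),
which mirrors the large-sample approximation a practitioner would run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from math import log
from typing import Union

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DGPConfigA",
    "DGPConfigB",
    "TrialDataset",
    "PotentialOutcomeTable",
    "TrueContrasts",
    "DEFAULT_ALPHA_3A",
    "DEFAULT_GAMMA_3A",
    "DEFAULT_BETA1_GRID",
    "REGIMES",
    "X2_EQUATION_TERMS",
    "Y_EQUATION_TERMS",
    "generate_scenario_a",
    "generate_scenario_b",
    "generate_potential_outcomes",
    "closed_form_truth",
]

#: Treatment regimes (t1, t2) contrasted against the never-treated (0, 0).
REGIMES = ((0, 0), (1, 0), (0, 1), (1, 1))

#: Instrument strengths on T1: the 3x3 grid is laid out so that instrument s
#: (1-based) has alpha cycling 2/5/10 within each block of three and gamma
#: constant per block — X3A_3 is the strongest T1-only instrument, X3A_7 the
#: strongest T2-only instrument, X3A_9 strongest on both.
DEFAULT_ALPHA_3A = tuple(np.tile([log(2.0), log(5.0), log(10.0)], 3))
DEFAULT_GAMMA_3A = tuple(np.repeat([log(2.0), log(5.0), log(10.0)], 3))

#: Confounder-association sweep for the near-IV scenario.
DEFAULT_BETA1_GRID = (0.01, 0.05, 0.1, 0.2, 0.3)

#: Terms allowed in the X2 and Y structural linear predictors.  The
#: instruments are deliberately absent: the exclusion restriction is built
#: into the code path, not merely into default coefficient values.
X2_EQUATION_TERMS = ("t1", "x1")
Y_EQUATION_TERMS = ("t1", "t2", "t1:t2", "x1", "x2")


def _check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"coefficient {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class _BaseConfig:
    n: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if int(self.n) < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")
        for f in dataclasses.fields(self):
            if f.name in ("n", "seed"):
                continue
            _check_finite(f.name, getattr(self, f.name))

    def replace(self, **changes):
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DGPConfigA(_BaseConfig):
    """Structural coefficients of the perfect-IV scenario (all log-odds)."""

    alpha_3a: tuple = DEFAULT_ALPHA_3A
    gamma_3a: tuple = DEFAULT_GAMMA_3A
    intercept_t1: float = -10.0
    intercept_x2: float = -1.0
    intercept_t2: float = -10.0
    intercept_y: float = -1.0
    coef_x1_t1: float = log(5.0)
    coef_t1_x2: float = log(5.0)
    coef_x1_x2: float = log(5.0)
    coef_t1_t2: float = log(1.2)
    coef_x1_t2: float = log(5.0)
    coef_x2_t2: float = log(2.0)
    coef_t1_y: float = log(1.2)
    coef_t2_y: float = log(1.5)
    coef_t1t2_y: float = log(1.5)
    coef_x1_y: float = log(5.0)
    coef_x2_y: float = log(2.0)

    def validate(self) -> None:
        super().validate()
        if len(self.alpha_3a) != 9 or len(self.gamma_3a) != 9:
            raise ValueError(
                "alpha_3a and gamma_3a must each have exactly 9 entries"
            )

    @property
    def x3_names(self) -> tuple:
        return tuple(f"x3_{s}" for s in range(1, 10))


@dataclass(frozen=True)
class DGPConfigB(_BaseConfig):
    """Structural coefficients of the near-IV scenario (all log-odds except
    ``beta1``, the mean shift of X3B per unit of X1)."""

    beta1: float = 0.1
    coef_x3b_t1: float = log(10.0)
    coef_x3b_t2: float = log(10.0)
    intercept_t1: float = -6.0
    intercept_x2: float = -1.0
    intercept_t2: float = -7.0
    intercept_y: float = -0.5
    coef_x1_t1: float = log(2.0)
    coef_t1_x2: float = log(5.0)
    coef_x1_x2: float = log(2.0)
    coef_t1_t2: float = log(1.2)
    coef_x1_t2: float = log(5.0)
    coef_x2_t2: float = log(2.0)
    coef_t1_y: float = log(1.2)
    coef_t2_y: float = log(1.5)
    coef_t1t2_y: float = log(1.5)
    coef_x1_y: float = log(2.0)
    coef_x2_y: float = log(2.0)

    @property
    def x3_names(self) -> tuple:
        return ("x3b",)


DGPConfig = Union[DGPConfigA, DGPConfigB]


@dataclass(frozen=True)
class TrialDataset:
    """One generated replicate of observed data.

    ``x3`` is an (n, k) matrix: nine standard-normal instrument columns in
    scenario A, a single near-IV column in scenario B. ``x3_names`` gives the
    column labels used in CSV output and adjustment sets.
    """

    x1: np.ndarray
    x3: np.ndarray
    t1: np.ndarray
    x2: np.ndarray
    t2: np.ndarray
    y: np.ndarray
    x3_names: tuple

    def __post_init__(self):
        n = len(self.x1)
        for name in ("t1", "x2", "t2", "y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        if self.x3.shape != (n, len(self.x3_names)):
            raise ValueError("x3 shape inconsistent with x3_names")

    @property
    def n(self) -> int:
        return len(self.x1)

    def column(self, name: str) -> np.ndarray:
        """Return a named column (``x1``, ``t1``, ``x2``, ``t2``, ``y`` or
        one of ``x3_names``)."""
        if name in ("x1", "t1", "x2", "t2", "y"):
            return getattr(self, name)
        if name in self.x3_names:
            return self.x3[:, self.x3_names.index(name)]
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        cols = {"x1": self.x1}
        for j, name in enumerate(self.x3_names):
            cols[name] = self.x3[:, j]
        cols.update(t1=self.t1, x2=self.x2, t2=self.t2, y=self.y)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialDataset":
        x3_names = tuple(c for c in frame.columns if c.startswith("x3"))
        return cls(
            x1=frame["x1"].to_numpy(),
            x3=frame[list(x3_names)].to_numpy(dtype=float).reshape(len(frame), -1),
            t1=frame["t1"].to_numpy(),
            x2=frame["x2"].to_numpy(),
            t2=frame["t2"].to_numpy(),
            y=frame["y"].to_numpy(),
            x3_names=x3_names,
        )


@dataclass(frozen=True)
class PotentialOutcomeTable:
    """Per-subject potential outcomes under the four treatment regimes."""

    x1: np.ndarray
    x2_t1_0: np.ndarray
    x2_t1_1: np.ndarray
    y_00: np.ndarray
    y_10: np.ndarray
    y_01: np.ndarray
    y_11: np.ndarray

    @property
    def n(self) -> int:
        return len(self.x1)

    def contrasts(self) -> "TrueContrasts":
        """Monte-Carlo contrasts E[Y^{t1,t2}] - E[Y^{0,0}] from this table."""
        e00 = float(np.mean(self.y_00))
        return TrueContrasts(
            d10=float(np.mean(self.y_10)) - e00,
            d01=float(np.mean(self.y_01)) - e00,
            d11=float(np.mean(self.y_11)) - e00,
        )


@dataclass(frozen=True)
class TrueContrasts:
    """The three counterfactual mean differences, on the probability scale."""

    d10: float
    d01: float
    d11: float

    def as_tuple(self) -> tuple:
        return (self.d10, self.d01, self.d11)


# ---------------------------------------------------------------------------
# structural linear predictors
# ---------------------------------------------------------------------------

def _lp_x2(config: DGPConfig, t1, x1):
    # terms: X2_EQUATION_TERMS only — no instrument enters
    return config.intercept_x2 + config.coef_t1_x2 * t1 + config.coef_x1_x2 * x1


def _lp_y(config: DGPConfig, t1, t2, x1, x2):
    # terms: Y_EQUATION_TERMS only — no instrument enters
    return (
        config.intercept_y
        + config.coef_t1_y * t1
        + config.coef_t2_y * t2
        + config.coef_t1t2_y * t1 * t2
        + config.coef_x1_y * x1
        + config.coef_x2_y * x2
    )


def _lp_t1(config: DGPConfig, x1, x3):
    lp = config.intercept_t1 + config.coef_x1_t1 * x1
    if isinstance(config, DGPConfigA):
        return lp + x3 @ np.asarray(config.alpha_3a, dtype=float)
    return lp + config.coef_x3b_t1 * x3[:, 0]


def _lp_t2(config: DGPConfig, t1, x1, x2, x3):
    lp = (
        config.intercept_t2
        + config.coef_t1_t2 * t1
        + config.coef_x1_t2 * x1
        + config.coef_x2_t2 * x2
    )
    if isinstance(config, DGPConfigA):
        return lp + x3 @ np.asarray(config.gamma_3a, dtype=float)
    return lp + config.coef_x3b_t2 * x3[:, 0]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _generate(config: DGPConfig) -> TrialDataset:
    # One stream per replicate, consumed in the fixed order
    # X1 -> X3 -> T1 -> X2 -> T2 -> Y, so identical configs reproduce
    # bit-identical data regardless of execution order elsewhere.
    config.validate()
    n = int(config.n)
    rng = np.random.default_rng(config.seed)
    x1 = rng.binomial(1, 0.5, n)
    if isinstance(config, DGPConfigA):
        x3 = rng.standard_normal((n, 9))
    else:
        x3 = (config.beta1 * x1 + rng.standard_normal(n)).reshape(n, 1)
    t1 = rng.binomial(1, expit(_lp_t1(config, x1, x3)))
    x2 = rng.binomial(1, expit(_lp_x2(config, t1, x1)))
    t2 = rng.binomial(1, expit(_lp_t2(config, t1, x1, x2, x3)))
    y = rng.binomial(1, expit(_lp_y(config, t1, t2, x1, x2)))
    return TrialDataset(x1=x1, x3=x3, t1=t1, x2=x2, t2=t2, y=y,
                        x3_names=config.x3_names)


def generate_scenario_a(config: DGPConfigA) -> TrialDataset:
    """Generate one observed dataset under the perfect-IV scenario."""
    if not isinstance(config, DGPConfigA):
        raise TypeError("generate_scenario_a requires a DGPConfigA")
    return _generate(config)


def generate_scenario_b(config: DGPConfigB) -> TrialDataset:
    """Generate one observed dataset under the near-IV scenario."""
    if not isinstance(config, DGPConfigB):
        raise TypeError("generate_scenario_b requires a DGPConfigB")
    return _generate(config)


def generate_potential_outcomes(config: DGPConfig) -> PotentialOutcomeTable:
    """Simulate per-subject potential outcomes under all four regimes.

    Instruments affect only treatment assignment, so they are irrelevant to
    the potential outcomes and are not drawn.  Draws are independent
    Bernoulli per regime: only the marginal means matter for the contrasts,
    so no cross-world coupling of the four outcomes is implied.
    """
    config.validate()
    n = int(config.n)
    rng = np.random.default_rng(config.seed)
    x1 = rng.binomial(1, 0.5, n).astype(np.int8)
    x2_pot = {}
    for t1 in (0, 1):
        p = expit(_lp_x2(config, t1, x1))
        x2_pot[t1] = rng.binomial(1, p).astype(np.int8)
    y_pot = {}
    for t1, t2 in REGIMES:
        p = expit(_lp_y(config, t1, t2, x1, x2_pot[t1]))
        y_pot[(t1, t2)] = rng.binomial(1, p).astype(np.int8)
    return PotentialOutcomeTable(
        x1=x1,
        x2_t1_0=x2_pot[0],
        x2_t1_1=x2_pot[1],
        y_00=y_pot[(0, 0)],
        y_10=y_pot[(1, 0)],
        y_01=y_pot[(0, 1)],
        y_11=y_pot[(1, 1)],
    )


def closed_form_truth(config: DGPConfig) -> TrueContrasts:
    """Exact counterfactual contrasts by summation over (X1, X2).

    E[Y^{t1,t2}] = sum_{x1} 0.5 * sum_{x2} P(X2=x2 | t1, x1) * expit(lp_y);
    deterministic and independent of ``n`` and ``seed``.
    """
    config.validate()

    def ey(t1: int, t2: int) -> float:
        total = 0.0
        for x1 in (0, 1):
            p_x2 = expit(_lp_x2(config, t1, x1))
            for x2 in (0, 1):
                w = p_x2 if x2 == 1 else 1.0 - p_x2
                total += 0.5 * w * expit(_lp_y(config, t1, t2, x1, x2))
        return float(total)

    e00 = ey(0, 0)
    return TrueContrasts(d10=ey(1, 0) - e00, d01=ey(0, 1) - e00,
                         d11=ey(1, 1) - e00)
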