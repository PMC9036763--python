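"""Data-generating processes: determinism, marginals, truths, exclusion."""

import dataclasses
from math import log

import numpy as np
import pytest
from scipy.special import expit

from gcompbias import (
    DGPConfigA,
    DGPConfigB,
    TrialDataset,
    closed_form_truth,
    generate_potential_outcomes,
    generate_scenario_a,
    generate_scenario_b,
)
from gcompbias.dgp import (
    DEFAULT_ALPHA_3A,
    DEFAULT_GAMMA_3A,
    X2_EQUATION_TERMS,
    Y_EQUATION_TERMS,
)

NULL_EFFECT = dict(coef_t1_y=0.0, coef_t2_y=0.0, coef_t1t2_y=0.0,
                   coef_t1_x2=0.0)


@pytest.mark.parametrize("config,gen", [
    (DGPConfigA(n=2_000, seed=7), generate_scenario_a),
    (DGPConfigB(n=2_000, seed=7, beta1=0.2), generate_scenario_b),
])
def test_same_seed_gives_identical_dataset(config, gen):
    a, b = gen(config), gen(config)
    for col in ("x1", "t1", "x2", "t2", "y"):
        np.testing.assert_array_equal(a.column(col), b.column(col))
    np.testing.assert_array_equal(a.x3, b.x3)


@pytest.mark.parametrize("bad", [
    DGPConfigA(n=0),
    DGPConfigA(n=1_000, intercept_y=float("nan")),
    DGPConfigA(n=1_000, alpha_3a=(1.0, 2.0)),
    DGPConfigB(n=-3),
    DGPConfigB(n=1_000, beta1=float("inf")),
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        bad.validate()


def test_scenario_a_marginals():
    data = generate_scenario_a(DGPConfigA(n=100_000, seed=1))
    assert abs(data.x1.mean() - 0.5) < 0.01
    # instruments are iid standard normal
    assert np.all(np.abs(data.x3.mean(axis=0)) < 0.02)
    assert np.all(np.abs(data.x3.var(axis=0) - 1.0) < 0.05)
    assert set(np.unique(data.t1)) <= {0, 1}
    assert set(np.unique(data.y)) <= {0, 1}


def test_treatment_prevalence_matches_independent_resimulation():
    """P(T1=1), P(T2=1) agree with a brute-force oracle drawn on a
    different RNG stream using direct expit evaluation."""
    n = 1_000_000
    cfg = DGPConfigA(n=n, seed=5)
    data = generate_scenario_a(cfg)

    rs = np.random.RandomState(987_654)  # legacy stream, independent
    x1 = rs.binomial(1, 0.5, n)
    x3 = rs.standard_normal((n, 9))
    p_t1 = expit(-10 + log(5) * x1 + x3 @ np.array(DEFAULT_ALPHA_3A))
    t1 = rs.binomial(1, p_t1)
    x2 = rs.binomial(1, expit(-1 + log(5) * t1 + log(5) * x1))
    p_t2 = expit(-10 + log(1.2) * t1 + log(5) * x1 + log(2) * x2
                 + x3 @ np.array(DEFAULT_GAMMA_3A))
    t2 = rs.binomial(1, p_t2)

    for obs, oracle in ((data.t1, t1), (data.t2, t2)):
        p = oracle.mean()
        mc_se = np.sqrt(2 * p * (1 - p) / n)
        assert abs(obs.mean() - p) < 3 * mc_se


@pytest.mark.parametrize("beta1,expected", [
    # corr(X3B, X1) = 0.5*beta1 / sqrt(1 + 0.25*beta1^2) for Bern(0.5) X1
    (0.0, 0.0),
    (0.3, 0.148),
])
def test_scenario_b_near_iv_confounder_correlation(beta1, expected):
    data = generate_scenario_b(DGPConfigB(n=100_000, seed=3, beta1=beta1))
    corr = np.corrcoef(data.x3[:, 0], data.x1)[0, 1]
    assert abs(corr - expected) < 0.02


def test_scenario_b_minimal_dataset():
    data = generate_scenario_b(DGPConfigB(n=1, seed=0, beta1=0.5))
    assert data.n == 1
    assert data.x3.shape == (1, 1)
    for col in ("x1", "t1", "x2", "t2", "y"):
        assert data.column(col).shape == (1,)


def test_potential_outcome_table_shape_and_binary():
    table = generate_potential_outcomes(DGPConfigA(n=10, seed=0))
    assert table.n == 10
    for name in ("x2_t1_0", "x2_t1_1", "y_00", "y_10", "y_01", "y_11"):
        col = getattr(table, name)
        assert col.shape == (10,)
        assert set(np.unique(col)) <= {0, 1}


def test_null_treatment_effect_gives_null_contrasts():
    cfg = DGPConfigA(n=500_000, seed=4, **NULL_EFFECT)
    assert closed_form_truth(cfg).as_tuple() == (0.0, 0.0, 0.0)
    mc = generate_potential_outcomes(cfg).contrasts()
    tol = 3 * np.sqrt(2 * 0.25 / cfg.n)
    assert all(abs(d) < tol for d in mc.as_tuple())


@pytest.mark.parametrize("cfg", [
    DGPConfigA(n=2_000_000, seed=21),
    DGPConfigB(n=2_000_000, seed=22, beta1=0.1),
])
def test_closed_form_truth_matches_simulated_potential_outcomes(cfg):
    """Oracle equivalence: exact summation vs brute-force simulation."""
    exact = np.array(closed_form_truth(cfg).as_tuple())
    mc = np.array(generate_potential_outcomes(cfg).contrasts().as_tuple())
    tol = 4 * np.sqrt(2 * 0.25 / cfg.n)
    assert np.all(np.abs(exact - mc) < tol)


def test_scenario_a_truth_values():
    """Frozen values from exact summation over (X1, X2); the single-year
    contrasts agree with large-sample simulation to two decimals."""
    t = closed_form_truth(DGPConfigA())
    assert 100 * t.d10 == pytest.approx(8.3177, abs=1e-3)
    assert 100 * t.d01 == pytest.approx(7.9932, abs=1e-3)
    assert 100 * t.d11 == pytest.approx(22.9674, abs=1e-3)


def test_exclusion_restriction_is_structural():
    """Instruments appear in no X2/Y equation term and cannot move the
    counterfactual truth."""
    for name in [f"x3_{s}" for s in range(1, 10)] + ["x3b", "x3"]:
        assert name not in X2_EQUATION_TERMS
        assert name not in Y_EQUATION_TERMS
    base = closed_form_truth(DGPConfigA())
    rescaled = closed_form_truth(
        DGPConfigA(alpha_3a=tuple(np.zeros(9)), gamma_3a=tuple(np.ones(9)))
    )
    assert base.as_tuple() == rescaled.as_tuple()
    assert (closed_form_truth(DGPConfigB(beta1=0.01)).as_tuple()
            == closed_form_truth(DGPConfigB(beta1=0.3)).as_tuple())


def test_dataset_csv_round_trip(tmp_path):
    data = generate_scenario_a(DGPConfigA(n=50, seed=9))
    frame = data.to_frame()
    assert list(frame.columns) == (
        ["x1"] + [f"x3_{s}" for s in range(1, 10)] + ["t1", "x2", "t2", "y"]
    )
    path = tmp_path / "trial.csv"
    frame.to_csv(path, index=False)
    import pandas as pd

    back = TrialDataset.from_frame(pd.read_csv(path))
    np.testing.assert_array_equal(back.y, data.y)
    np.testing.assert_allclose(back.x3, data.x3)


def test_config_replace_preserves_other_fields():
    cfg = DGPConfigB(n=10, seed=1, beta1=0.2)
    cfg2 = cfg.replace(n=99, seed=5)
    assert (cfg2.n, cfg2.seed, cfg2.beta1) == (99, 5, 0.2)
    assert dataclasses.asdict(cfg)["coef_x3b_t1"] == cfg2.coef_x3b_t1
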