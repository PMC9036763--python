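import numpy as np
import pytest

from gcompbias import (
    AdjustmentSet,
    DGPConfigA,
    DGPConfigB,
    fit_g_models,
    generate_scenario_a,
    generate_scenario_b,
)


@pytest.fixture(scope="session")
def big_a():
    """One large scenario-A replicate, shared by consistency checks."""
    return generate_scenario_a(DGPConfigA(n=200_000, seed=11))


@pytest.fixture(scope="session")
def medium_b():
    return generate_scenario_b(DGPConfigB(n=100_000, seed=12, beta1=0.3))


@pytest.fixture(scope="session")
def fitted_correct(big_a):
    """Correctly specified fit (adjusting for the true confounder x1)."""
    return fit_g_models(big_a, AdjustmentSet(("x1",)))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
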