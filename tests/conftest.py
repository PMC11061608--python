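import numpy as np
import pandas as pd
import pytest

from sclcy import ExpressionMatrix, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    values = pd.DataFrame(
        rng.normal(size=(6, 4)),
        index=["ASCL1", "NEUROD1", "POU2F3", "YAP1", "SMARCA4", "GAPDH"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values=values)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=5))
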