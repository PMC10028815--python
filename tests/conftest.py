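import numpy as np
import pandas as pd
import pytest

from mimiclasso import cohort as ch
from mimiclasso.model import mimic_spec


@pytest.fixture(scope="session")
def tiny_partial():
    """A mid-sized partial-overlap cohort shared across tests."""
    design = ch.make_design("partial", 4000, 0.5, seed=101, preset="tiny")
    table, truth = ch.generate_cohort(design)
    return design, table, truth


@pytest.fixture(scope="session")
def tiny_spec(tiny_partial):
    design, _, _ = tiny_partial
    return mimic_spec(ch.DEFAULT_INDICATORS, design.predictors)


@pytest.fixture(scope="session")
def regression_data():
    """Plain lasso-equivalent data: one observed outcome, 20 predictors."""
    rng = np.random.default_rng(5)
    n, p = 1000, 20
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:3] = [0.5, -0.4, 0.3]
    y = X @ beta + rng.standard_normal(n)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["y"] = y
    return df, beta
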