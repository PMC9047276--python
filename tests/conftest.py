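import numpy as np
import pandas as pd
import pytest

from hteforest.data import CohortTable, Variable, VariableDictionary
from hteforest.simulate import default_config, generate_cohort

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def small_dictionary(covariates=("x1", "x2")):
    entries = [
        Variable("id", "categorical", "", "identifier"),
        Variable("study", "categorical", "", "study"),
        Variable("arm", "binary", "", "treatment"),
    ]
    entries += [Variable(c, "continuous", "", "covariate") for c in covariates]
    entries += [
        Variable("mace", "binary", "", "outcome"),
        Variable("event_time", "continuous", "years", "time"),
    ]
    return VariableDictionary(entries)


def synthetic_cohort(n=400, p=2, seed=0, tau_fn=None, base=0.3,
                     studies=("A", "B")):
    """Small randomized cohort with optional planted CATE tau_fn(X)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    arm = rng.integers(0, 2, size=n)
    p_event = np.full(n, base)
    if tau_fn is not None:
        p_event = np.clip(base + arm * tau_fn(X), 0.01, 0.99)
    y = rng.binomial(1, p_event)
    cols = {f"x{i + 1}": X[:, i] for i in range(p)}
    df = pd.DataFrame({
        "id": [f"r{i}" for i in range(n)],
        "study": np.where(np.arange(n) % 2 == 0, studies[0], studies[-1]),
        "arm": arm.astype(float),
        **cols,
        "mace": y.astype(float),
        "event_time": rng.exponential(2.0, size=n),
    })
    dictionary = small_dictionary(tuple(cols))
    return CohortTable(df, dictionary)


@pytest.fixture
def tiny_cohort():
    return synthetic_cohort(n=200, p=2, seed=42)


@pytest.fixture(scope="session")
def table1_config():
    return default_config()


@pytest.fixture(scope="session")
def small_default_cohort(table1_config):
    """A 1/6-scale draw from the calibrated generator (n ~ 2008)."""
    return generate_cohort(table1_config.scaled(1 / 6), seed=11)
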