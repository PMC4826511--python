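import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import growthcontrasts as gc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort900() -> gc.SyntheticCohort:
    """A complete-case cohort of 900 children with a logistic outcome."""
    return gc.simulate_cohort(900, gc.OutcomeSpec(), seed=11)


@pytest.fixture(scope="session")
def Z900(cohort900) -> pd.DataFrame:
    return cohort900.data


@pytest.fixture(scope="session")
def reference() -> pd.DataFrame:
    return gc.synthetic_reference()


@pytest.fixture(scope="session")
def cutoffs() -> pd.DataFrame:
    return gc.synthetic_cutoffs()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
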