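import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caribou_pva.reference import (
    published_recruitment_model,
    published_survival_model,
)
from caribou_pva.synthetic_data import GeneratorConfig

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# One fixed seed for every stochastic check in the suite.
SEED = 20170725


@pytest.fixture(scope="session")
def survival_model():
    return published_survival_model()


@pytest.fixture(scope="session")
def recruitment_model():
    return published_recruitment_model()


@pytest.fixture()
def small_config():
    """A quick six-population design for smoke-level pipeline tests."""
    return GeneratorConfig(n_populations=6, years=8, seed=SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
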