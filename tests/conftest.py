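import numpy as np
import pytest

from gojirisk.data_model import DEFAULT_EXPOSURE_FACTORS, default_registry
from gojirisk.synthetic_data import (
    DEFAULT_PLANTATION,
    DEFAULT_SUPERMARKET,
    generate_concentrations,
    generate_survey,
)

#: conventional seed for every seeded stochastic check in the suite
SEED = 1234


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def factors():
    return DEFAULT_EXPOSURE_FACTORS


@pytest.fixture(scope="session")
def plantation_dataset():
    return generate_concentrations(DEFAULT_PLANTATION, SEED)


@pytest.fixture(scope="session")
def supermarket_dataset():
    return generate_concentrations(DEFAULT_SUPERMARKET, SEED)


@pytest.fixture(scope="session")
def survey_records():
    return generate_survey(558, seed=SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
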