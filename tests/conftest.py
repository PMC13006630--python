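import numpy as np
import pytest

from fedgait.cohort import CohortConfig, generate_cohort, generate_dataset
from fedgait.preprocess import carry_forward_bmi


@pytest.fixture(scope="session")
def default_cohort():
    """Complete (pre-missingness) default cohort, seed 0."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced cohort with missingness applied and BMI carried forward."""
    return carry_forward_bmi(generate_dataset(CohortConfig(n_participants=24, seed=3)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
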