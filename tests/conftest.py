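import numpy as np
import pytest

from pedree.synthetic import (
    CohortConfig, generate_cohort, generate_selection_benchmark,
    synthetic_bmi_reference, synthetic_wfl_reference,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-child synthetic cohort shared by fast tests."""
    return generate_cohort(CohortConfig(n=150, seed=11))


@pytest.fixture(scope="session")
def full_cohort():
    """The default-size (561) synthetic cohort used by scaled-down replicas."""
    return generate_cohort(CohortConfig(n=561, seed=1))


@pytest.fixture(scope="session")
def bmi_reference():
    return synthetic_bmi_reference()


@pytest.fixture(scope="session")
def wfl_reference():
    return synthetic_wfl_reference()


@pytest.fixture(scope="session")
def benchmark_problem():
    """13-variable selection benchmark: exactly 7 informative columns."""
    return generate_selection_benchmark(n=561, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
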