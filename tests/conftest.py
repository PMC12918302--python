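import numpy as np
import pytest

from releap.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4k-patient cohort at 10% outcome prevalence, shared across tests."""
    return generate_cohort(CohortConfig(n_patients=4_000, seed=42))


@pytest.fixture(scope="session")
def big_cohort():
    """50k-patient cohort for calibration / parameter-recovery checks."""
    return generate_cohort(CohortConfig(n_patients=50_000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
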