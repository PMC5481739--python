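import numpy as np
import pytest

from tscpipe.config import CohortConfig
from tscpipe.simulate import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_patients=12, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One small simulated cohort shared across read-only tests."""
    return generate_cohort(small_config)
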