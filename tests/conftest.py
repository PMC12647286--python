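import numpy as np
import pytest

from alpskit import CohortConfig, generate_cohort, default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def cohort():
    """Default 50-subject, two-session cohort at a fixed seed."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
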