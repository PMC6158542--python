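import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isletquant as iq

settings.register_profile(
    "det", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def rat_prep():
    """A mid-sized rat prep with full ground truth, shared across tests."""
    return iq.sample_prep("rat", 300, seed=20_24)


@pytest.fixture(scope="session")
def scheme():
    return iq.BinningScheme()


@pytest.fixture(scope="session")
def rat_curve():
    return iq.default_curve("rat")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
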