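import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from ndfmem.rate import RateModelParams, TrialProtocol
from ndfmem.ring import ConnectivitySet, RingParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def rate_params():
    """Reference homogeneous parameters: W_inh = c = 500, balanced start."""
    return RateModelParams(W_inh=500.0, W_exc0=500.0, c=500.0)


@pytest.fixture
def protocol():
    return TrialProtocol()


@pytest.fixture(scope="session")
def ring_params():
    """Full-size ring (standard parameter table)."""
    return RingParams()


@pytest.fixture(scope="session")
def small_ring_params():
    """Half-size ring for learning-session tests (same kernels in radians)."""
    return RingParams(N=32)


@pytest.fixture(scope="session")
def short_ring_params():
    """Half-size ring with a shortened delay for fast dynamical checks."""
    return RingParams(N=32, t_total=1500.0)


@pytest.fixture(scope="session")
def table1_conn(ring_params):
    return ConnectivitySet.from_params(ring_params)
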