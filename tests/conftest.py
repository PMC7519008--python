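import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genespin import Network, generate_ba_network

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def triangle() -> Network:
    return Network(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture(scope="session")
def path5() -> Network:
    return Network(5, [(0, 1), (1, 2), (2, 3), (3, 4)])


@pytest.fixture(scope="session")
def star6() -> Network:
    """Hub node 0 with five leaves."""
    return Network(6, [(0, i) for i in range(1, 6)])


@pytest.fixture(scope="session")
def single_edge() -> Network:
    return Network(2, [(0, 1)])


@pytest.fixture(scope="session")
def ba_small() -> Network:
    return generate_ba_network(10, 2, seed=3)


@pytest.fixture(scope="session")
def ba5000() -> Network:
    """The headline study network: N = 5000, m = 5."""
    return generate_ba_network(5000, 5, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
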