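import logging

import numpy as np
import pytest

from scasim.io_formats import SimConfig
from scasim.pipeline import make_fixture, simulate_discrete

logging.getLogger("scasim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def reference():
    """The standard 2000-peak x 500-cell reference with known statistics."""
    return make_fixture(npeak=2000, ncell=500, n_types=2, seed=0)


@pytest.fixture(scope="session")
def small_reference():
    return make_fixture(npeak=500, ncell=200, n_types=2, seed=1)


@pytest.fixture(scope="session")
def discrete_run(reference):
    """One discrete-mode simulation with full details, shared across tests."""
    config = SimConfig(mode="discrete", covariance=np.eye(5), ncell=500, seed=1)
    return simulate_discrete(reference, config, details=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
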