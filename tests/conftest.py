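import numpy as np
import pytest

from pgktz import SimulationConfig, build_canonical_network, simulate


@pytest.fixture(scope="session")
def default_network():
    return build_canonical_network()


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def endpoint_states(default_network, default_config):
    """Final states of default 60 s runs at the three headline TZ doses (uM)."""
    return {
        tz: simulate(default_network, default_config, tz=tz).final_state
        for tz in (0.0, 0.05, 25.0)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240220)
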