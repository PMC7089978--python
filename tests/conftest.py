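import numpy as np
import pytest

from zmwfcs.photon_data import TTTRTrace
from zmwfcs.simulate import SimulationConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trace(rng):
    """A hand-sized valid photon trace."""
    n = 500
    macro = np.sort(rng.integers(0, 4_000_000, n))
    micro = rng.integers(0, 25_000, n)
    ch = np.zeros(n, np.int16)
    return TTTRTrace(macro, micro, ch, sync_rate=40e6, metadata={"dye": "Atto647N"})


@pytest.fixture(scope="session")
def short_sim_config():
    """Short no-sticking acquisition used by several pipeline tests."""
    return SimulationConfig(duration=8.0, rng_seed=42)


@pytest.fixture(scope="session")
def short_sim_trace(short_sim_config):
    return simulate_experiment(short_sim_config)
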