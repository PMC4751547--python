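import numpy as np
import pytest

from mugakit.synthetic import SimConfig, SimulatedPanel, simulate_panel


@pytest.fixture(scope="session")
def small_panel() -> SimulatedPanel:
    """Small default panel: 8 founders, 28 F1s, 2 outbreds, ~2300 markers."""
    return simulate_panel(SimConfig(seed=20151218, n_outbred=2))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
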