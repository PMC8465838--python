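import numpy as np
import pytest

import localte as lt


@pytest.fixture(scope="session")
def small_topology():
    """20-cell network, control geometry, fixed seeds."""
    return lt.make_topology(n=20, sigma_r=0.3, fraction_inhibitory=0.2,
                            topology_seed=11, label_seed=12)


@pytest.fixture(scope="session")
def short_simulation(small_topology):
    """20 cells, 20 s of activity with the default parameter set."""
    return lt.run_simulation(small_topology, duration=20_000.0, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
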