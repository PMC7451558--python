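import numpy as np
import pytest

from seedbox.synthetic import SimulationConfig, make_profiles, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """8 varieties, default config, fixed seed — shared read-only fixture."""
    cfg = SimulationConfig()
    profiles = make_profiles(8, seed=11)
    return simulate_experiment(cfg, profiles, seed=11), cfg, profiles


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
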