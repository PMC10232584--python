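import numpy as np
import pytest

from stresseeg.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_region_coupled_config():
    """Small two-region config with a known alpha envelope coupling."""
    return SimulationConfig(
        n_participants=1,
        n_epochs_per_condition=30,
        fs=256.0,
        regions=("precuneus L", "precuneus R"),
        baseline_coupling={(("precuneus L", "precuneus R"), "alpha"): 0.6},
        background_amplitude=0.3,
        random_seed=11,
    )


@pytest.fixture
def tiny_config():
    """Fast, effect-free config for smoke tests."""
    return SimulationConfig(
        n_participants=3,
        n_epochs_per_condition=6,
        fs=128.0,
        regions=("precuneus L", "precuneus R", "ACC L"),
        random_seed=5,
    )
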