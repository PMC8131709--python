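import numpy as np
import pytest

from echospecies.pulse import ChirpConfig, apply_fast_ramp, default_frc_grid, make_chirp
from echospecies.simulate import MesocosmDesign, simulate_mesocosm_dataset


@pytest.fixture(scope="session")
def chirp_config():
    return ChirpConfig()


@pytest.fixture(scope="session")
def replica(chirp_config):
    return apply_fast_ramp(make_chirp(chirp_config), chirp_config)


@pytest.fixture(scope="session")
def grid():
    return default_frc_grid()


@pytest.fixture(scope="session")
def mesocosm_dataset():
    """Full replication fixture: 140 training + 47 testing fish, 10 responses
    each, generated through the complete acoustic chain."""
    return simulate_mesocosm_dataset(MesocosmDesign(seed=11))


@pytest.fixture(scope="session")
def frc_table(mesocosm_dataset):
    return mesocosm_dataset[0]


@pytest.fixture(scope="session")
def tracks(mesocosm_dataset):
    return mesocosm_dataset[1]


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced design (direct spectral path) for fast structural tests."""
    design = MesocosmDesign(
        n_train_stickleback=6, n_train_whitefish=5,
        n_test_stickleback=3, n_test_whitefish=2,
        seed=3, acoustic_chain=False,
    )
    return simulate_mesocosm_dataset(design)
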