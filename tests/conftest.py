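import numpy as np
import pytest

from strainmosaic.config import SimConfig
from strainmosaic.simulate import simulate_study


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_sites=800, n_sv=60, seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free study conditions: no read error, guaranteed depth,
    fully homozygous, no repeats — classification should equal truth."""
    return SimConfig(n_sites=600, seq_error=0.0, min_depth=5,
                     homozygosity=1.0, repeat_fraction=0.0, n_repeats=0,
                     seed=23)


@pytest.fixture(scope="session")
def clean_study(clean_cfg):
    return simulate_study(clean_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
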