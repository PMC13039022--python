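import numpy as np
import pytest

from hepaseg.net import NetConfig
from hepaseg.phantoms import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_net_config():
    """Small network for fast structural tests; bottleneck dim 8."""
    return NetConfig(
        levels=2,
        channels_per_level=(4, 8),
        pool_factors=((2, 2, 2), (2, 2, 2)),
        codebook_k=8,
        ssm_state_size=4,
    )


@pytest.fixture
def small_phantom_config():
    return PhantomConfig(
        grid_shape=(24, 32, 32),
        spacing_mm=(1.0, 1.0, 1.0),
        liver_semiaxes_mm=(9.0, 12.0, 12.0),
        n_tumors=1,
        tumor_radius_range_mm=(3.0, 4.0),
        noise_sd=5.0,
        seed=7,
    )
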