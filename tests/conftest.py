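import numpy as np
import pytest

from swindiff.diffusion import build_linear_schedule
from swindiff.nn.denoiser import NetworkConfig, SwinDenoiser
from swindiff.phantom import PhantomConfig, generate_phantoms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_schedule():
    """T=5 chain with visible noise levels for brute-force oracles."""
    return build_linear_schedule(5, 0.1)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return NetworkConfig(
        base_channels=4, window_size=4, num_heads=2, groupnorm_groups=4, depth_preset="reduced"
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_net_cfg):
    return SwinDenoiser(tiny_net_cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def phantoms16():
    return generate_phantoms(PhantomConfig(n_images=16, side=32, seed=11))
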