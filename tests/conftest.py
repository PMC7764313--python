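import numpy as np
import pytest
from hypothesis import settings

import ardtnet as a

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_arch():
    """Reduced-scale architecture: k=6, 2 blocks, 64x64 input."""
    return a.ArchConfig(growth_rate=6, layers_per_block=6, num_blocks=2,
                        initial_channels=24, input_side=64)


@pytest.fixture(scope="session")
def micro_arch():
    """Smallest valid architecture, for fast forward/backward tests."""
    return a.ArchConfig(growth_rate=2, layers_per_block=2, num_blocks=2,
                        initial_channels=8, input_side=16)


@pytest.fixture(scope="session")
def micro_net(micro_arch):
    return a.ARDTDenseNet(micro_arch, seed=7)


@pytest.fixture(scope="session")
def synth_small():
    """Small in-memory synthetic dataset (fast to render)."""
    cfg = a.SynthConfig(n_per_class=6, image_side=96, seed=42)
    return cfg, a.make_manifest(cfg)
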