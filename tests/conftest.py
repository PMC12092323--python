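import numpy as np
import pytest

from rnadotseg import synthgen
from rnadotseg.netarch import NetworkConfig, build_network


@pytest.fixture(scope="session")
def tiny_model():
    """Small network used by several structural tests (deterministic init)."""
    return build_network(NetworkConfig(backbone_size="tiny", input_size=64,
                                       upscale_dropout=0.15), seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_patches():
    """Four tiny synthetic patches for training smoke tests."""
    from rnadotseg.experiments import make_synthetic_dataset
    return make_synthetic_dataset(4, (32, 32), seed=77, max_dots=4)


@pytest.fixture(scope="session")
def example_patch():
    return synthgen.generate_patch(shape=(96, 96), seed=2024)
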