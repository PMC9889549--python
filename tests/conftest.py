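import numpy as np
import pytest

from attnfuse.synthetic import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 balanced two-class samples with a fused (XOR) signal."""
    return generate_dataset(SynthConfig(n_samples=8, n_classes=2,
                                        signal_mode="fusion_xor", seed=1))


@pytest.fixture(scope="session")
def image_dataset():
    """Small image-signal dataset for variant and saliency tests."""
    return generate_dataset(SynthConfig(n_samples=30, n_classes=2,
                                        signal_mode="image_only", seed=3))
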