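import numpy as np
import pytest

from specfusenet.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """3 well-separated classes x 20 samples, fast enough for training tests."""
    return generate(SyntheticSpec(n_classes=3, samples_per_class=20, seed=1))


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 classes x 8 samples for smoke/contract tests."""
    return generate(SyntheticSpec(n_classes=2, samples_per_class=8,
                                  n_points=64, seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
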