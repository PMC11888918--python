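import numpy as np
import pytest

from emgmc import SyntheticSpec, generate_labeled_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """3 classes x 8 recordings, 3 channels, 512 samples: fast but separable."""
    spec = SyntheticSpec(
        n_classes=3, n_channels=3, n_samples=512, n_per_class=8, seed=11
    )
    return generate_labeled_dataset(spec)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The headline benchmark: 4 classes x 25 recordings, 4 channels, N=2048."""
    spec = SyntheticSpec(
        n_classes=4, n_channels=4, n_samples=2048, n_per_class=25, seed=7
    )
    return generate_labeled_dataset(spec)
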