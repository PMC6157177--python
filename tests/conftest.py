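import numpy as np
import pytest

from cnmp.datasets import generate_dataset, tiny_spec


@pytest.fixture(scope="session")
def tiny_dataset():
    """60-image noiseless 4-class fixture (64x64) shared across tests."""
    return generate_dataset(tiny_spec(n_per_class=15, noise_sd=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
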