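import numpy as np
import pytest

from dynparc import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two synthetic subjects with 3 planted switching states."""
    volumes, mask, truth = generate_dataset(
        n_subjects=2, n_states=3, T=400, snr=2.0, seed=11)
    return volumes, mask, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
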