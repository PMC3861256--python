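import numpy as np
import pytest

from skyline import ground_truth
from skyline.scene_synth import make_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Twenty synthetic scenes with simulated estimate sets."""
    return make_corpus(20, width=96, height=72, seed=7)


@pytest.fixture(scope="session")
def small_densities(small_corpus):
    return {
        rec.id: ground_truth.fit_density(ground_truth.remove_outliers(est))
        for rec, est in small_corpus
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
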