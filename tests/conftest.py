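import numpy as np
import pytest

from toxprof.synthetic import random_library


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_library():
    """20 random 20-mer barcodes at pairwise Hamming distance >= 3."""
    return random_library(20, seed=11)
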