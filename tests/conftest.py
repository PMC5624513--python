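import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_triplet_labels(rng, n_obs=None, max_bins=4):
    """Three aligned random label vectors with 2..max_bins states each."""
    n = int(rng.integers(20, 1001)) if n_obs is None else n_obs
    bins = rng.integers(2, max_bins + 1, size=3)
    return [rng.integers(0, b, size=n) for b in bins]
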