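import numpy as np
import pytest

from psdf import DiscreteDataset, FeaturePrior


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_pair():
    """Four items, concordant for the first three, discordant last."""
    x1 = np.array([[1, 1], [1, 1], [3, 3], [3, 2]])
    x2 = np.array([[1, 1], [1, 2], [3, 3], [1, 1]])
    d1 = DiscreteDataset(x1, ("a", "b", "c", "d"), ("f1", "f2"))
    d2 = DiscreteDataset(x2, ("a", "b", "c", "d"), ("g1", "g2"))
    return d1, d2


@pytest.fixture
def toy_priors(toy_pair):
    d1, d2 = toy_pair
    return FeaturePrior.from_dataset(d1), FeaturePrior.from_dataset(d2)
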