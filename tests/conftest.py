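import numpy as np
import pytest

from spatialadmix import FrequencyMatrix, pairwise_distances
from spatialadmix.simulate import lattice_coords


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def grid_distances():
    """Normalized pairwise distances on a 4x4 unit lattice."""
    return pairwise_distances(lattice_coords((4, 4)), normalize=True)


@pytest.fixture
def haploid_fm(rng):
    """Small haploid 0/1 frequency matrix (frequencies are indicators)."""
    return FrequencyMatrix(rng.integers(0, 2, size=(5, 40)).astype(float))
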