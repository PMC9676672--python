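import numpy as np
import pytest

from plectax import Alignment, SimParams, simulate


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment((("a", "ACGT"), ("b", "AGGT"), ("c", "AC-T"), ("d", "TGGA")))


@pytest.fixture
def two_cluster_dataset():
    """Two clearly separated clusters of five sequences each."""
    return simulate(SimParams(k=2, n_per_group=5, seq_length=200,
                              d_within=0.005, d_between=0.2, seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220039)
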