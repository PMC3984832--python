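import numpy as np
import pytest

from exospect.pipeline import train_prototypes
from exospect.simulate import GeneModelParams, simulate_corpus, simulate_gene


@pytest.fixture(scope="session")
def strong_gene():
    """One synthetic gene with maximal 3-base periodicity (seed 0)."""
    return simulate_gene(GeneModelParams(periodicity_strength=1.0, seed=0))


@pytest.fixture(scope="session")
def small_corpus():
    """Five annotated genes (w = 0.9) for quick pipeline tests."""
    pairs, _ = simulate_corpus(5, GeneModelParams(periodicity_strength=0.9), seed=1)
    return pairs


@pytest.fixture(scope="session")
def trained_prototypes(small_corpus):
    return train_prototypes(small_corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
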