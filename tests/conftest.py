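import numpy as np
import pytest

from bindmodes import GenomeSequence, make_annotation, make_genome


@pytest.fixture(scope="session")
def small_genome() -> GenomeSequence:
    """50-kb seeded random genome at 60% G+C (halophile-like composition)."""
    return make_genome(50_000, 0.6, seed=11)


@pytest.fixture(scope="session")
def small_annotation(small_genome):
    """85%-coding annotation over the small genome."""
    return make_annotation(small_genome, n_genes=40, coding_fraction=0.85, seed=12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
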