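import numpy as np
import pytest

from teasv import (DetectionThresholds, ReferenceGenome, ScoringScheme,
                   SequenceRecord, SimulatedGenomeSpec, build_genome_indexes,
                   make_synthetic_ltr_te, simulate_genome)


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme()


@pytest.fixture(scope="session")
def thresholds():
    return DetectionThresholds()


@pytest.fixture(scope="session")
def small_genome():
    """50-kb single-chromosome random genome shared across tests."""
    return simulate_genome(SimulatedGenomeSpec((50_000,), 0.36, 11))


@pytest.fixture(scope="session")
def small_genome_indexes(small_genome, scoring):
    return build_genome_indexes(small_genome, scoring)


@pytest.fixture(scope="session")
def ltr_te():
    return make_synthetic_ltr_te(99)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
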