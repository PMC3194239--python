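import numpy as np
import pytest

from metaseval.community import ReferenceGenome, Taxonomy
from metaseval.seq import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def ref(genome_id: str, sequence: str, species=None, genus=None, phylum="p0"):
    """Shorthand reference-genome constructor for fixtures."""
    return ReferenceGenome(
        genome_id, sequence,
        Taxonomy(genome_id, species or f"sp_{genome_id}",
                 genus or f"ge_{genome_id}", phylum))


@pytest.fixture
def small_genome(rng):
    return ref("gA", random_sequence(rng, 5000))


@pytest.fixture
def two_genomes(rng):
    return [ref("gA", random_sequence(rng, 5000)),
            ref("gB", random_sequence(rng, 5000))]
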