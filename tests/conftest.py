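import numpy as np
import pytest

from chimorf.seqio import GenomeSequence
from chimorf.simulate import (generate_reference, plant_chimeric_orfs,
                              simulate_coverage)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture(scope="session")
def default_fixture():
    """One 100 kb fixture with 5 chimeric + 20 decoy ORFs and coverage."""
    genome, feats = generate_reference(1)
    genome, truth = plant_chimeric_orfs(genome, feats, 2)
    track = simulate_coverage(
        genome, 3, 23.0,
        [(r.start, r.length) for r in truth.planted_zero_regions])
    return genome, feats, truth, track


@pytest.fixture
def linear_genome():
    def make(seq: str, circular: bool = False) -> GenomeSequence:
        return GenomeSequence("g", seq, circular=circular)
    return make
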