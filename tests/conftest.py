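import numpy as np
import pytest

from endocycle.bootstrap import generate_bootstrap_genomes
from endocycle.genome import (
    BindingSite,
    Genome,
    HouseholdGene,
    RegulatoryGene,
    random_bits,
)
from endocycle.regulation import StageTable


@pytest.fixture(scope="session")
def bootstrap_pair():
    return generate_bootstrap_genomes()


@pytest.fixture(scope="session")
def bootstrap_genome(bootstrap_pair):
    return bootstrap_pair[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240209)


@pytest.fixture(scope="session")
def stage_table():
    return StageTable()


def random_genome(rng, n_beads=None, B=20) -> Genome:
    """A random genome mixing all three bead kinds."""
    if n_beads is None:
        n_beads = int(rng.integers(0, 40))
    beads = []
    for _ in range(n_beads):
        kind = rng.integers(0, 3)
        if kind == 0:
            beads.append(HouseholdGene())
        elif kind == 1:
            beads.append(BindingSite(random_bits(rng, B)))
        else:
            beads.append(
                RegulatoryGene(
                    type_id=int(rng.integers(1, 12)),
                    binding_seq=random_bits(rng, B),
                    signal_peptide=random_bits(rng, 2),
                    weight=int(rng.integers(-3, 4)),
                    threshold=int(rng.integers(-2, 6)),
                )
            )
    return Genome(beads, B=B)
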