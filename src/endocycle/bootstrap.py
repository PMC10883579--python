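"""The primitive bootstrap holobiont genome.

Host and symbiont start from one engineered genome of 64 beads: 50 passive
household genes and a 14-bead regulatory repertoire (the five core genes
g1..g5 plus nine binding sites) wired as a primitive but viable cell
cycle. The circuit (an artifact construction; only its summary properties
are contractual) is:

* g5 (position 0, replicated first) and g1 (position 63, replicated last)
  are constitutively expressed (threshold -2). Their products double in
  copy number once their bead is behind the replication fork, so g1's
  product is a *replication-completion clock*: 2 copies exactly when the
  genome is fully replicated.
* g2 is driven by g5's product through one medium-affinity site; it
  flickers on and off, carrying the G1 -> S transition.
* g3 is the S-exit trigger: six low-affinity sites all matched to g1's
  product with threshold 6, an AND-gate over six rare binding events whose
  per-site probability roughly doubles when g1's dosage doubles. Before
  replication finishes the gate almost never fires; afterwards it fires
  within some tens of timesteps -- a primitive, stochastic replication
  checkpoint.
* g4 is the M driver: two high-affinity sites for the products of g3
  (weight 2) and g2 (weight 1) with threshold 3, so M can only follow a
  step in which both the S-exit trigger and the S carrier were expressed.

The resulting stage patterns over (g1..g5) are G1=10001, S=11001,
G2=11101, M=11011 -- the package's default :class:`~endocycle.regulation.StageTable`.
"""

from __future__ import annotations

from typing import Optional

from .genome import (
    DEFAULT_B,
    BindingSite,
    Genome,
    HouseholdGene,
    RegulatoryGene,
)

__all__ = ["generate_bootstrap_genomes", "core_sequences"]


def _bits(ones: set[int], n: int = DEFAULT_B) -> tuple[int, ...]:
    return tuple(1 if i in ones else 0 for i in range(n))


def core_sequences(B: int = DEFAULT_B) -> dict[int, tuple[int, ...]]:
    """Binding sequences of the five core genes, mutually far apart
    (pairwise Hamming distance >= 10) so cross-binding is negligible."""
    if B != DEFAULT_B:
        raise ValueError("the bootstrap circuit is wired for B=20")
    all_on = set(range(B))
    return {
        1: _bits(set()),                      # s1: all zeros (the clock)
        2: _bits(all_on - {0, 1, 2, 3, 4}),
        3: _bits(all_on - {5, 6, 7, 8, 9}),
        4: _bits(all_on - {10, 11, 12, 13, 14}),
        5: _bits(all_on - {15, 16, 17, 18, 19}),
    }


def _flip(seq: tuple[int, ...], positions: set[int]) -> tuple[int, ...]:
    return tuple(b ^ 1 if i in positions else b for i, b in enumerate(seq))


def generate_bootstrap_genomes(
    config=None, rng=None, household: int = 50
) -> tuple[Genome, Genome]:
    """Return the identical primitive (host, symbiont) genome pair.

    L = 64 with 50 household beads by default. The construction is fully
    deterministic; ``config`` and ``rng`` are accepted for interface
    uniformity (a run config may override the household count through
    ``config.bootstrap_household`` if present).
    """
    if config is not None:
        household = getattr(config, "bootstrap_household", household)
    s = core_sequences()
    sp = (0, 0)  # products stay in the compartment where they are encoded

    g5 = RegulatoryGene(5, s[5], sp, weight=1, threshold=-2)
    g2 = RegulatoryGene(2, s[2], sp, weight=1, threshold=1)
    # g3's weight 2 with g4's threshold 3 makes M strictly require the
    # S-exit trigger: no combination of +1 cross-bindings can reach 3.
    g3 = RegulatoryGene(3, s[3], sp, weight=2, threshold=6)
    g4 = RegulatoryGene(4, s[4], sp, weight=1, threshold=3)
    g1 = RegulatoryGene(1, s[1], sp, weight=1, threshold=-2)

    site_g2 = BindingSite(_flip(s[5], {0, 1}))  # d=2 to g5's product
    # six low-affinity clock-reading sites: three at d=4, three at d=5
    clock_sites = [
        BindingSite(_flip(s[1], {0, 1, 2, 3})),
        BindingSite(_flip(s[1], {4, 5, 6, 7})),
        BindingSite(_flip(s[1], {8, 9, 10, 11})),
        BindingSite(_flip(s[1], {12, 13, 14, 15, 16})),
        BindingSite(_flip(s[1], {15, 16, 17, 18, 19})),
        BindingSite(_flip(s[1], {2, 5, 8, 11, 14})),
    ]
    site_g4_a = BindingSite(s[3])  # d=0 to g3's product
    site_g4_b = BindingSite(s[2])  # d=0 to g2's product

    beads = (
        [g5, site_g2, g2]
        + clock_sites
        + [g3, site_g4_a, site_g4_b, g4]
        + [HouseholdGene() for _ in range(household)]
        + [g1]
    )
    host = Genome(beads, B=DEFAULT_B)
    symbiont = Genome(beads, B=DEFAULT_B)
    return host, symbiont
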