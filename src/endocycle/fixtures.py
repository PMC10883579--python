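"""Hand-wired synthetic genomes and holobionts for tests and assays.

All fixtures are engineered constructions, produced programmatically:

* the bootstrap host/symbiont pair (see :mod:`endocycle.bootstrap`);
* a **nonviable** genome (household beads only -- never reaches M, never
  dies);
* a **constitutive-M** genome whose expression always shows the M
  pattern, so an isolated cell dies within a step or two of decoding it;
* a **host-control** holobiont: the symbiont's S carrier (g2) is
  silenced (threshold 5, unreachable), so the symbiont's cell cycle runs
  only while the host's dual-localized (signal peptide 11) g2 product is
  delivered -- knocking out host-to-symbiont targeting kills the clone;
* a **symbiont-control** holobiont: the host's M driver needs +4 but its
  own circuit supplies only +2; the missing +2 comes from a constitutive
  symbiont gene (type 6) whose product carries a host-localization
  peptide (10) -- knocking out symbiont-to-host targeting blocks host
  division.
"""

from __future__ import annotations

from dataclasses import replace

from .bootstrap import core_sequences, generate_bootstrap_genomes
from .genome import (
    DEFAULT_B,
    BindingSite,
    Genome,
    HouseholdGene,
    RegulatoryGene,
)

__all__ = [
    "nonviable_genome",
    "constitutive_m_genome",
    "host_control_pair",
    "symbiont_control_pair",
    "make_test_fixtures",
]


def nonviable_genome(L: int = 64) -> Genome:
    """Household beads only: no expression, no division, no death."""
    return Genome([HouseholdGene() for _ in range(L)], B=DEFAULT_B)


def constitutive_m_genome() -> Genome:
    """Shows the M pattern (11011) constitutively; dies in isolation."""
    s = core_sequences()
    sp = (0, 0)
    genes = [
        RegulatoryGene(1, s[1], sp, weight=1, threshold=-2),
        RegulatoryGene(2, s[2], sp, weight=1, threshold=-2),
        RegulatoryGene(3, s[3], sp, weight=1, threshold=5),  # off: no sites
        RegulatoryGene(4, s[4], sp, weight=1, threshold=-2),
        RegulatoryGene(5, s[5], sp, weight=1, threshold=-2),
    ]
    return Genome(genes + [HouseholdGene() for _ in range(59)], B=DEFAULT_B)


def host_control_pair() -> tuple[Genome, Genome]:
    """(host, symbiont) where the symbiont's cycle requires host-to-symbiont
    signaling.

    The host is the bootstrap genome with g2 dual-localized (11). The
    symbiont is the bootstrap genome with g2's threshold raised to 5 --
    unreachable for its single +1 site -- so the symbiont's S/G2/M
    patterns can only show their g2 bit through the host's bit-identical
    delivered product (which also substitutes for the symbiont's own g2
    product at the M driver's site).
    """
    host, symbiont = generate_bootstrap_genomes()
    host_beads = [
        replace(b, signal_peptide=(1, 1))
        if isinstance(b, RegulatoryGene) and b.type_id == 2
        else b
        for b in host
    ]
    sym_beads = [
        replace(b, threshold=5)
        if isinstance(b, RegulatoryGene) and b.type_id == 2
        else b
        for b in symbiont
    ]
    return Genome(host_beads, B=host.B), Genome(sym_beads, B=symbiont.B)


def symbiont_control_pair() -> tuple[Genome, Genome]:
    """(host, symbiont) where host division requires symbiont-to-host
    signaling.

    The host's M driver g4 gets threshold 4 and its second input site is
    rewired to a sequence no host product matches, so the host's own
    circuit supplies at most +2 (g3) plus stray +1 cross-bindings. The
    symbiont carries an extra constitutive gene of type 6 with that
    sequence, weight +2 and a host-localization peptide (10): host M
    fires only while the symbiont's signal is delivered.
    """
    host, symbiont = generate_bootstrap_genomes()
    s = core_sequences()
    # signal sequence at Hamming distance >= 9 from every core product's
    # sequence, so no host product can stand in for the symbiont signal
    signal_seq = tuple(
        1 if i in {0, 1, 2, 5, 6, 7, 10, 11, 15, 16} else 0 for i in range(DEFAULT_B)
    )

    host_beads = []
    for b in host:
        if isinstance(b, BindingSite) and b.seq == s[2]:
            host_beads.append(BindingSite(signal_seq))  # g4's second input
        elif isinstance(b, RegulatoryGene) and b.type_id == 4:
            # threshold 4: +2 from g3 plus +2 from the symbiont signal;
            # stray +1 cross-bindings can never complete the sum
            host_beads.append(replace(b, threshold=4))
        else:
            host_beads.append(b)
    signal_gene = RegulatoryGene(6, signal_seq, (1, 0), weight=2, threshold=-2)
    sym_beads = list(symbiont) + [signal_gene]
    return Genome(host_beads, B=host.B), Genome(sym_beads, B=symbiont.B)


def make_test_fixtures(rng=None) -> dict:
    """The full fixture suite keyed by name."""
    boot_host, boot_sym = generate_bootstrap_genomes(rng=rng)
    return {
        "bootstrap": (boot_host, boot_sym),
        "nonviable": nonviable_genome(),
        "constitutive_m": constitutive_m_genome(),
        "host_control": host_control_pair(),
        "symbiont_control": symbiont_control_pair(),
    }
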