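"""Host-symbiont molecular interference.

Three coupling channels connect the compartments of a holobiont:

* **Leakage** -- every expressed gene's product leaks passively between
  host and each symbiont with probability ``l`` (default 0.01) per gene
  per symbiont per timestep, so the influx into a symbiont scales with
  the host's expressed-gene count and the influx into the host scales
  with the expressed genes of all symbionts combined.
* **Targeting** -- an expressed gene's 2-bit signal peptide routes its
  product: ``10`` host compartment only, ``01`` every symbiont, ``00``
  the encoding compartment, ``11`` both. Cross-compartment deliveries are
  tagged ``targeted``; absence from the native compartment (a one-hot
  peptide pointing away) is enforced by the cell itself
  (:meth:`endocycle.cell_cycle.Cell.native_products`).
* **Gene transfer** -- a newly divided host (symbiont) can receive each
  regulatory-gene bead of each symbiont (of the host) with probability
  ``mu_t`` per gene (default 2.0e-5), as a copy (donor keeps the bead) or
  a cut (donor loses it), 50/50, inserted at a uniform random position.

Each channel can be switched off per direction; the disabled-leakage and
disabled-signaling growth assays are those switches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .cell_cycle import Cell
from .genome import Bead, Genome, RegulatoryGene
from .regulation import Localization, Product

__all__ = [
    "InterferenceConfig",
    "apply_leakage",
    "apply_targeting",
    "gene_transfer",
]


@dataclass(frozen=True)
class InterferenceConfig:
    """Rates and per-direction switches for the three channels."""

    leakage_rate: float = 0.01
    leakage_host_to_symbiont: bool = True
    leakage_symbiont_to_host: bool = True
    targeting_host_to_symbiont: bool = True
    targeting_symbiont_to_host: bool = True
    transfer_rate: float = 2.0e-5
    transfer_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.leakage_rate <= 1.0):
            raise ValueError(f"leakage rate {self.leakage_rate} outside [0, 1]")
        if not (0.0 <= self.transfer_rate <= 1.0):
            raise ValueError(f"transfer rate {self.transfer_rate} outside [0, 1]")

    @classmethod
    def all_off(cls) -> "InterferenceConfig":
        return cls(
            leakage_rate=0.0,
            leakage_host_to_symbiont=False,
            leakage_symbiont_to_host=False,
            targeting_host_to_symbiont=False,
            targeting_symbiont_to_host=False,
            transfer_rate=0.0,
            transfer_enabled=False,
        )

    def with_knockout(self, **kwargs) -> "InterferenceConfig":
        return replace(self, **kwargs)


def apply_leakage(host: Cell, symbionts: Sequence[Cell], cfg: InterferenceConfig, rng) -> int:
    """Deliver passively leaked products into foreign pools; returns the
    number of leak events.

    Each expressed host gene leaks into each symbiont independently with
    probability ``l`` per timestep; each expressed symbiont gene leaks
    into the host with probability ``l``. One delivery carries one copy.
    Foreign products never re-leak.
    """
    l = cfg.leakage_rate
    if l <= 0.0 or not host.alive:
        return 0
    events = 0
    alive_symbionts = [s for s in symbionts if s.alive]
    # each (expressed gene, partner cell) pair leaks independently with
    # probability l; drawn as a binomial count over the pairs plus a
    # uniform sample of which pairs fired -- the same distribution,
    # without per-pair draws
    if cfg.leakage_host_to_symbiont and alive_symbionts:
        n_expr = sum(host.expression)
        n_pairs = n_expr * len(alive_symbionts)
        k = int(rng.binomial(n_pairs, l)) if n_pairs else 0
        if k:
            genes = host.expressed_genes()
            for flat in rng.choice(n_pairs, size=k, replace=False):
                gene = genes[int(flat) // len(alive_symbionts)]
                sym = alive_symbionts[int(flat) % len(alive_symbionts)]
                sym.foreign_pool.add(_delivery(host, gene, Localization.LEAKED))
            events += k
    if cfg.leakage_symbiont_to_host:
        for sym in alive_symbionts:
            n_expr = sum(sym.expression)
            k = int(rng.binomial(n_expr, l)) if n_expr else 0
            if k:
                genes = sym.expressed_genes()
                for gi in rng.choice(n_expr, size=k, replace=False):
                    host.foreign_pool.add(
                        _delivery(sym, genes[int(gi)], Localization.LEAKED)
                    )
                events += k
    return events


def _delivery(source: Cell, gene: RegulatoryGene, localization: Localization) -> Product:
    return Product(
        origin=source.origin,
        type_id=gene.type_id,
        seq=gene.binding_seq,
        weight=gene.weight,
        copies=1,
        localization=localization,
    )


def apply_targeting(host: Cell, symbionts: Sequence[Cell], cfg: InterferenceConfig) -> int:
    """Deliver signal-peptide-routed products across compartments.

    A host product whose peptide has the symbiont bit set (``01`` or
    ``11``) is delivered to every living symbiont; a symbiont product
    with the host bit set is delivered to the host. Deliveries carry one
    copy and are tagged ``targeted``; a disabled direction drops them.
    Returns the number of deliveries made.
    """
    events = 0
    alive_symbionts = [s for s in symbionts if s.alive]
    if cfg.targeting_host_to_symbiont and host.alive and host.genome.has_routing_peptides():
        for gene in host.expressed_genes():
            if gene.signal_peptide[1]:
                for sym in alive_symbionts:
                    sym.foreign_pool.add(_delivery(host, gene, Localization.TARGETED))
                    events += 1
    if cfg.targeting_symbiont_to_host and host.alive:
        for sym in alive_symbionts:
            if not sym.genome.has_routing_peptides():
                continue
            for gene in sym.expressed_genes():
                if gene.signal_peptide[0]:
                    host.foreign_pool.add(_delivery(sym, gene, Localization.TARGETED))
                    events += 1
    return events


def gene_transfer(
    host: Cell,
    symbionts: Sequence[Cell],
    cfg: InterferenceConfig,
    rng,
    just_divided_host: bool = False,
    just_divided_symbionts: Iterable[Cell] = (),
) -> int:
    """Endosymbiotic gene transfer at division; returns the event count.

    A newly divided host draws each regulatory-gene bead of each symbiont
    with probability ``mu_t``; a newly divided symbiont draws from the
    host. Transfers move the bare gene bead (no flanking sites): copy
    keeps the donor bead, cut removes it; the insertion position is
    uniform over the recipient's L+1 slots. Genomes are replaced in place
    on the affected cells.
    """
    if not cfg.transfer_enabled or cfg.transfer_rate <= 0.0:
        return 0
    events = 0
    if just_divided_host:
        for donor in symbionts:
            if donor.alive:
                events += _transfer_between(donor, host, cfg.transfer_rate, rng)
    for recipient in just_divided_symbionts:
        if recipient.alive:
            events += _transfer_between(host, recipient, cfg.transfer_rate, rng)
    return events


def _per_bead_expression(cell: Cell) -> list:
    """Expression flags aligned with the bead list (None for non-genes)."""
    flags: list = []
    it = iter(cell.expression)
    for b in cell.genome:
        flags.append(next(it, False) if isinstance(b, RegulatoryGene) else None)
    return flags


def _transfer_between(donor: Cell, recipient: Cell, mu_t: float, rng) -> int:
    moved: list[tuple[int, RegulatoryGene, bool]] = []
    for gi in donor.genome.gene_positions():
        if rng.random() < mu_t:
            cut = rng.random() < 0.5
            moved.append((gi, donor.genome[gi], cut))
    if not moved:
        return 0
    cut_positions = {gi for gi, _, cut in moved if cut}
    if cut_positions:
        flags = _per_bead_expression(donor)
        donor_beads = [b for i, b in enumerate(donor.genome) if i not in cut_positions]
        donor.genome = Genome(donor_beads, B=donor.genome.B)
        donor.expression = tuple(
            f for i, f in enumerate(flags) if i not in cut_positions and f is not None
        )
        donor.fork = min(donor.fork, donor.genome.L)
    rec_beads: list[Bead] = list(recipient.genome)
    rec_flags = _per_bead_expression(recipient)
    for _, gene, _ in moved:
        pos = int(rng.integers(0, len(rec_beads) + 1))
        rec_beads.insert(pos, gene)
        rec_flags.insert(pos, False)  # transferred genes start unexpressed
    recipient.genome = Genome(rec_beads, B=recipient.genome.B)
    recipient.expression = tuple(f for f in rec_flags if f is not None)
    return len(moved)
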