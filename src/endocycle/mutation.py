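"""Genome mutation operators applied at cell division.

All rates are per division. The operators act in a fixed order for
reproducibility: per-bead structural events (duplication, deletion,
relocation, each Bernoulli per bead of the pre-mutation bead list), then
per-genome innovations (a fresh random binding site or a fresh regulatory
gene with a new non-core type id), then per-element value mutations (bit
flips on binding sequences and signal peptides, +/-1 steps on weights and
thresholds, clamped to their configured ranges). Household beads undergo
only the structural operators.

Default rates (per division):

==========  =========  =============================================
mu_B        3.3e-5     per bit of every gene/site binding sequence
mu_S        1.0e-5     per signal-peptide bit
mu_w        1.67e-4    per gene, regulatory weight +/-1
mu_theta    1.67e-4    per gene, activation threshold +/-1
mu_dup      1.67e-4    per bead, tandem duplication
mu_del      1.67e-4    per bead, deletion
mu_rel      1.67e-4    per bead, relocation to a random position
mu_b_in     1.67e-3    per genome, binding-site innovation
mu_r_in     1.67e-4    per genome, regulatory-gene innovation
==========  =========  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome import (
    THRESHOLD_RANGE,
    WEIGHT_RANGE,
    Bead,
    BindingSite,
    Genome,
    HouseholdGene,
    RegulatoryGene,
    random_bits,
)

__all__ = [
    "MutationRates",
    "mutate_genome",
    "innovate_gene",
    "innovate_site",
    "expected_event_counts",
    "Mutator",
]


@dataclass(frozen=True)
class MutationRates:
    mu_B: float = 3.3e-5
    mu_S: float = 1.0e-5
    mu_w: float = 1.67e-4
    mu_theta: float = 1.67e-4
    mu_dup: float = 1.67e-4
    mu_del: float = 1.67e-4
    mu_rel: float = 1.67e-4
    mu_b_in: float = 1.67e-3
    mu_r_in: float = 1.67e-4

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def zero(cls) -> "MutationRates":
        return cls(0, 0, 0, 0, 0, 0, 0, 0, 0)

    def scaled(self, factor: float) -> "MutationRates":
        return MutationRates(**{k: min(1.0, v * factor) for k, v in self.__dict__.items()})


def _clamp(v: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, v))


class _TypeIdCounter:
    """Process-wide source of fresh non-core type ids.

    Core types 1..5 are never created de novo; a run-scoped counter can be
    passed explicitly for strict reproducibility across processes.
    """

    def __init__(self, start: int = 6):
        self.next_id = start

    def fresh(self) -> int:
        v = self.next_id
        self.next_id += 1
        return v

    def bump_past(self, type_id: int) -> None:
        if type_id >= self.next_id:
            self.next_id = type_id + 1


def innovate_site(rng, B: int) -> BindingSite:
    return BindingSite(random_bits(rng, B))


def innovate_gene(rng, B: int, counter: _TypeIdCounter) -> RegulatoryGene:
    """A de-novo regulatory gene: fresh non-core type id, uniform random
    binding sequence, uniform weight and threshold, signal peptide 00."""
    return RegulatoryGene(
        type_id=counter.fresh(),
        binding_seq=random_bits(rng, B),
        signal_peptide=(0, 0),
        weight=int(rng.integers(WEIGHT_RANGE[0], WEIGHT_RANGE[1] + 1)),
        threshold=int(rng.integers(THRESHOLD_RANGE[0], THRESHOLD_RANGE[1] + 1)),
    )


def _draw_subset(rng, n: int, p: float) -> set[int]:
    """A uniform random subset of range(n) in which each element appears
    independently with probability p (drawn as a binomial count plus a
    uniform position sample, equivalent to per-element Bernoulli)."""
    if p <= 0.0 or n == 0:
        return set()
    k = int(rng.binomial(n, p))
    if k == 0:
        return set()
    return set(int(i) for i in rng.choice(n, size=k, replace=False))


def mutate_genome(
    genome: Genome,
    rates: MutationRates,
    rng,
    counter: _TypeIdCounter | None = None,
    counts: dict[str, int] | None = None,
) -> Genome:
    """One round of divisional mutation; returns a new Genome.

    Structural events are drawn against the pre-mutation bead list:
    duplication inserts the copy immediately downstream of the original,
    deletion removes the bead, relocation removes it and reinserts it at
    a uniformly random position. Innovations insert at a uniformly random
    position. Value mutations apply to the post-structural bead list.
    Deletion takes precedence over relocation over duplication when one
    bead draws several structural events. When ``counts`` is given, the
    number of realized events per operator is accumulated into it.
    """
    if counter is None:
        counter = _global_counter
    for b in genome:
        if isinstance(b, RegulatoryGene):
            counter.bump_past(b.type_id)

    L = genome.L
    del_set = _draw_subset(rng, L, rates.mu_del)
    rel_set = _draw_subset(rng, L, rates.mu_rel)
    dup_set = _draw_subset(rng, L, rates.mu_dup)

    beads: list[Bead] = []
    relocated: list[Bead] = []
    n_dup = n_del = n_rel = 0
    for i, b in enumerate(genome):
        if i in del_set:
            n_del += 1
            continue
        if i in rel_set:
            relocated.append(b)
            n_rel += 1
            continue
        beads.append(b)
        if i in dup_set:
            beads.append(b)
            n_dup += 1
    for b in relocated:
        beads.insert(int(rng.integers(0, len(beads) + 1)), b)

    n_site_in = n_gene_in = 0
    if rates.mu_b_in > 0 and rng.random() < rates.mu_b_in:
        beads.insert(int(rng.integers(0, len(beads) + 1)), innovate_site(rng, genome.B))
        n_site_in = 1
    if rates.mu_r_in > 0 and rng.random() < rates.mu_r_in:
        beads.insert(int(rng.integers(0, len(beads) + 1)), innovate_gene(rng, genome.B, counter))
        n_gene_in = 1

    # value mutations on the post-structural list, drawn per class
    seq_owners = [i for i, b in enumerate(beads) if not isinstance(b, HouseholdGene)]
    gene_owners = [i for i, b in enumerate(beads) if isinstance(b, RegulatoryGene)]
    B = genome.B
    edits: dict[int, dict] = {}

    for flat in _draw_subset(rng, len(seq_owners) * B, rates.mu_B):
        idx, bit = seq_owners[flat // B], flat % B
        edits.setdefault(idx, {}).setdefault("seq_bits", []).append(bit)
    for flat in _draw_subset(rng, len(gene_owners) * 2, rates.mu_S):
        idx, bit = gene_owners[flat // 2], flat % 2
        edits.setdefault(idx, {}).setdefault("sp_bits", []).append(bit)
    for j in _draw_subset(rng, len(gene_owners), rates.mu_w):
        edits.setdefault(gene_owners[j], {})["dw"] = 1 if rng.random() < 0.5 else -1
    for j in _draw_subset(rng, len(gene_owners), rates.mu_theta):
        edits.setdefault(gene_owners[j], {})["dth"] = 1 if rng.random() < 0.5 else -1

    n_bits = n_sp = n_w = n_th = 0
    for idx, ed in edits.items():
        b = beads[idx]
        if isinstance(b, BindingSite):
            seq = list(b.seq)
            for bit in ed.get("seq_bits", ()):
                seq[bit] ^= 1
                n_bits += 1
            beads[idx] = BindingSite(tuple(seq))
            continue
        seq = list(b.binding_seq)
        for bit in ed.get("seq_bits", ()):
            seq[bit] ^= 1
            n_bits += 1
        sp = list(b.signal_peptide)
        for bit in ed.get("sp_bits", ()):
            sp[bit] ^= 1
            n_sp += 1
        w, th = b.weight, b.threshold
        if "dw" in ed:
            w = _clamp(w + ed["dw"], *WEIGHT_RANGE)
            n_w += 1
        if "dth" in ed:
            th = _clamp(th + ed["dth"], *THRESHOLD_RANGE)
            n_th += 1
        beads[idx] = replace(
            b, binding_seq=tuple(seq), signal_peptide=tuple(sp), weight=w, threshold=th
        )

    if (
        not edits
        and n_dup == n_del == n_rel == n_site_in == n_gene_in == 0
    ):
        if counts is not None:
            pass  # nothing to record
        return genome  # untouched: keep the instance (and its caches)

    if counts is not None:
        for key, n in (
            ("dup", n_dup), ("del", n_del), ("rel", n_rel),
            ("bit_flip", n_bits), ("sp_flip", n_sp),
            ("weight", n_w), ("threshold", n_th),
            ("site_innovation", n_site_in), ("gene_innovation", n_gene_in),
        ):
            counts[key] = counts.get(key, 0) + n
    return Genome(beads, B=genome.B)


_global_counter = _TypeIdCounter()


class Mutator:
    """Callable genome -> genome bound to one rate set, rng and type-id
    counter; the form :func:`~endocycle.cell_cycle.divide_cell` expects."""

    def __init__(self, rates: MutationRates, rng, counter: _TypeIdCounter | None = None):
        self.rates = rates
        self.rng = rng
        self.counter = counter if counter is not None else _TypeIdCounter()

    def __call__(self, genome: Genome) -> Genome:
        return mutate_genome(genome, self.rates, self.rng, self.counter)


def expected_event_counts(genome: Genome, rates: MutationRates) -> dict[str, float]:
    """Per-division expectation of each operator's event count (test oracle)."""
    st = genome.stats()
    seq_bits = genome.B * (st.gene_count + st.site_count)
    return {
        "dup": genome.L * rates.mu_dup,
        "del": genome.L * rates.mu_del,
        "rel": genome.L * rates.mu_rel,
        "bit_flip": seq_bits * rates.mu_B,
        "sp_flip": 2 * st.gene_count * rates.mu_S,
        "weight": st.gene_count * rates.mu_w,
        "threshold": st.gene_count * rates.mu_theta,
        "site_innovation": rates.mu_b_in,
        "gene_innovation": rates.mu_r_in,
    }
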