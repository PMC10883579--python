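"""Stochastic product-site binding and Boolean expression dynamics.

Each timestep the products of expressed genes compete for binding sites.
The affinity of a product for a site decays geometrically with the Hamming
distance between their bit vectors and scales linearly with the product's
copy number (gene dosage),

    a = c * s**d * copies,        d = Hamming(product.seq, site.seq)

with defaults c = 10, s = 0.5. Every site independently draws one occupant
from the categorical distribution with unnormalized mass 1 for "empty" and
mass a_p for each product p, so even a perfectly matching product binds
with probability a/(1+a) < 1. Expression is then Boolean: a gene turns on
when the summed weights of products bound in its upstream regulatory
region reach its activation threshold.

The joint expression of the five core gene types g1..g5 is decoded against
a :class:`StageTable` of four 5-bit patterns to give the cell-cycle stage
(G1, S, G2 or M). Foreign products (leaked or signal-peptide-targeted from
the partner compartment) act like native products everywhere, and also
count toward the core pattern -- but only if their sequence is bit-identical
to a native copy of that core type, so diverged core genes shield a cell
from having its stage dictated by its partner.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .genome import BindingSite, Genome, RegulatoryGene

__all__ = [
    "DEFAULT_AFFINITY_C",
    "DEFAULT_AFFINITY_S",
    "Stage",
    "StageTable",
    "Origin",
    "Localization",
    "Product",
    "ProductPool",
    "binding_affinity",
    "occupancy_distribution",
    "sample_site_occupancy",
    "sample_occupancy",
    "update_expression",
    "core_pattern",
    "decode_stage",
]

DEFAULT_AFFINITY_C = 10.0
DEFAULT_AFFINITY_S = 0.5


class Stage(enum.IntEnum):
    G1 = 0
    S = 1
    G2 = 2
    M = 3


class Origin(str, enum.Enum):
    HOST = "host"
    SYMBIONT = "symbiont"


class Localization(str, enum.Enum):
    NATIVE = "native"
    LEAKED = "leaked"
    TARGETED = "targeted"


@dataclass(frozen=True)
class StageTable:
    """Four distinct 5-bit core-expression patterns, one per stage.

    The default table (an artifact convention; any four distinct patterns
    admitting a viable bootstrap genome would do) is
    G1=10001, S=11001, G2=11101, M=11011, read as the expression bits of
    core types g1..g5 left to right: g1 and g5 are constitutive in the
    bootstrap circuit, g2 carries S, g3 flags the S-exit checkpoint and
    g4 drives M.
    """

    patterns: tuple[tuple[int, ...], ...] = (
        (1, 0, 0, 0, 1),
        (1, 1, 0, 0, 1),
        (1, 1, 1, 0, 1),
        (1, 1, 0, 1, 1),
    )

    def __post_init__(self) -> None:
        pats = tuple(tuple(int(b) for b in p) for p in self.patterns)
        if len(pats) != 4 or any(len(p) != 5 for p in pats):
            raise ValueError("StageTable needs four 5-bit patterns")
        if len(set(pats)) != 4:
            raise ValueError("StageTable patterns must be pairwise distinct")
        object.__setattr__(self, "patterns", pats)
        object.__setattr__(
            self, "_lookup", {p: Stage(i) for i, p in enumerate(pats)}
        )

    def __getitem__(self, stage: Stage) -> tuple[int, ...]:
        return self.patterns[Stage(stage)]

    @classmethod
    def from_strings(cls, g1: str, s: str, g2: str, m: str) -> "StageTable":
        return cls(tuple(tuple(int(c) for c in p) for p in (g1, s, g2, m)))


@dataclass(frozen=True)
class Product:
    """A regulatory product present in one cell for one timestep."""

    origin: Origin
    type_id: int
    seq: tuple[int, ...]
    weight: int
    copies: int = 1
    localization: Localization = Localization.NATIVE

    def with_copies(self, copies: int) -> "Product":
        return replace(self, copies=copies)


class ProductPool:
    """The multiset of products present in a cell this timestep.

    Records with identical identity (origin, type, sequence, weight,
    localization) merge additively in copy number.
    """

    __slots__ = ("_records",)

    def __init__(self, products: Iterable[Product] = ()):
        self._records: dict[tuple, Product] = {}
        for p in products:
            self.add(p)

    @staticmethod
    def _key(p: Product) -> tuple:
        return (p.origin, p.type_id, p.seq, p.weight, p.localization)

    def add(self, p: Product) -> None:
        if p.copies < 1:
            raise ValueError("product copies must be >= 1")
        k = self._key(p)
        if k in self._records:
            self._records[k] = self._records[k].with_copies(self._records[k].copies + p.copies)
        else:
            self._records[k] = p

    def extend(self, products: Iterable[Product]) -> None:
        for p in products:
            self.add(p)

    @property
    def products(self) -> list[Product]:
        return list(self._records.values())

    def total_copies(self) -> int:
        return sum(p.copies for p in self._records.values())

    def foreign(self) -> list[Product]:
        return [p for p in self._records.values() if p.localization is not Localization.NATIVE]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __bool__(self) -> bool:
        return bool(self._records)


def stays_native(origin: Origin, peptide: Sequence[int]) -> bool:
    """Whether a product remains present in its encoding compartment.

    ``00`` stays put; ``11`` is present in both compartments; ``10`` is
    present only in the host and ``01`` only in symbionts, so a one-hot
    peptide pointing away from the encoding compartment removes the
    product from its own cell.
    """
    host_bit, sym_bit = int(peptide[0]), int(peptide[1])
    if (host_bit, sym_bit) == (0, 0):
        return True
    return bool(host_bit) if origin is Origin.HOST else bool(sym_bit)


from functools import lru_cache


@lru_cache(maxsize=65536)
def _hamming_cached(a: tuple, b: tuple) -> int:
    return sum(x != y for x, y in zip(a, b))


def _hamming(a: Sequence[int], b: Sequence[int]) -> int:
    if len(a) != len(b):
        raise ValueError(f"bit-length mismatch: {len(a)} vs {len(b)}")
    if isinstance(a, tuple) and isinstance(b, tuple):
        return _hamming_cached(a, b)
    return sum(x != y for x, y in zip(a, b))


def binding_affinity(
    product: Product,
    site: BindingSite,
    c: float = DEFAULT_AFFINITY_C,
    s: float = DEFAULT_AFFINITY_S,
) -> float:
    """Unnormalized binding mass ``c * s**d * copies`` of a product for a site."""
    d = _hamming(product.seq, site.seq)
    return c * (s ** d) * product.copies


def occupancy_distribution(
    site: BindingSite,
    pool: ProductPool,
    c: float = DEFAULT_AFFINITY_C,
    s: float = DEFAULT_AFFINITY_S,
) -> list[tuple[Optional[Product], float]]:
    """Exact categorical occupancy distribution of one site.

    Returns ``[(None, p_empty), (product, p_bound), ...]`` with
    probabilities proportional to mass 1 for the empty outcome and the
    binding affinity for each product.
    """
    masses: list[tuple[Optional[Product], float]] = [(None, 1.0)]
    for p in pool:
        masses.append((p, binding_affinity(p, site, c=c, s=s)))
    z = sum(m for _, m in masses)
    return [(p, m / z) for p, m in masses]


def sample_site_occupancy(
    site: BindingSite,
    pool: ProductPool,
    rng,
    c: float = DEFAULT_AFFINITY_C,
    s: float = DEFAULT_AFFINITY_S,
) -> Optional[Product]:
    """Draw the product (or None) occupying one site this timestep."""
    if not pool:
        return None
    outcomes = [None] + list(pool)
    masses = [1.0] + [binding_affinity(p, site, c=c, s=s) for p in outcomes[1:]]
    z = sum(masses)
    u = rng.random() * z
    acc = 0.0
    for out, m in zip(outcomes, masses):
        acc += m
        if u < acc:
            return out
    return outcomes[-1]  # guard against float round-off


def sample_occupancy(
    genome: Genome,
    pool: ProductPool,
    rng,
    c: float = DEFAULT_AFFINITY_C,
    s: float = DEFAULT_AFFINITY_S,
) -> dict[int, Optional[Product]]:
    """Sample occupancy independently for every binding site of the genome."""
    occ: dict[int, Optional[Product]] = {}
    for i in genome.site_positions():
        occ[i] = sample_site_occupancy(genome[i], pool, rng, c=c, s=s)
    return occ


def update_expression(
    genome: Genome, occupancy: Mapping[int, Optional[Product]]
) -> tuple[bool, ...]:
    """Boolean expression of every regulatory gene given site occupancy.

    Gene *g* is expressed next step iff the sum of bound products' weights
    over its upstream regulatory region reaches ``g.threshold``. Returns a
    tuple aligned with ``genome.gene_positions()``.
    """
    out: list[bool] = []
    for gi in genome.gene_positions():
        gene: RegulatoryGene = genome[gi]
        total = 0
        for si in genome.regulatory_region(gi):
            p = occupancy.get(si)
            if p is not None:
                total += p.weight
        out.append(total >= gene.threshold)
    return tuple(out)


def core_pattern(
    expression: Sequence[bool], genome: Genome, pool: ProductPool
) -> tuple[int, ...]:
    """The 5-bit core pattern defining the cell-cycle stage.

    Bit *k* (for core type k+1) is set iff a native gene of that type is
    expressed, or a foreign product of that type in the pool is
    bit-identical to at least one native gene of the same type.
    """
    bits = [0, 0, 0, 0, 0]
    native_seqs: dict[int, set[tuple[int, ...]]] = {}
    for expr, gi in zip(expression, genome.gene_positions()):
        gene: RegulatoryGene = genome[gi]
        if 1 <= gene.type_id <= 5:
            native_seqs.setdefault(gene.type_id, set()).add(gene.binding_seq)
            if expr:
                bits[gene.type_id - 1] = 1
    for p in pool.foreign():
        if 1 <= p.type_id <= 5 and p.seq in native_seqs.get(p.type_id, ()):
            bits[p.type_id - 1] = 1
    return tuple(bits)


def decode_stage(bits: Sequence[int], table: StageTable) -> Optional[Stage]:
    """Map a 5-bit core pattern to its stage, or None if it matches none."""
    lookup = getattr(table, "_lookup", None)
    if lookup is not None:
        hit = lookup.get(bits if isinstance(bits, tuple) else tuple(bits))
        if hit is not None:
            return hit
        return lookup.get(tuple(int(b) for b in bits))
    t = tuple(int(b) for b in bits)
    for stage in Stage:
        if table[stage] == t:
            return stage
    return None
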