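"""Beads-on-a-string genomes.

A genome is an ordered list of discrete *beads* of three kinds:

* :class:`RegulatoryGene` -- codes for a regulatory product with a binding
  sequence (a fixed-length bit vector), a 2-bit signal peptide, a signed
  regulatory weight and an activation threshold;
* :class:`BindingSite` -- a cis-regulatory element carrying only a bit
  vector; a gene is regulated by the contiguous run of binding sites
  immediately upstream of it;
* :class:`HouseholdGene` -- a passive marker bead that contributes to genome
  length (and hence replication time) but never to expression dynamics.

Genome size ``L`` is the total bead count and the regulatory repertoire
``R`` counts the non-household beads (genes plus binding sites).

Genomes serialize to a line-based text format (one bead per line) with the
header ``#endocycle-genome v1 B=<int>``; see :func:`parse_genome` and
:func:`serialize_genome`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

__all__ = [
    "DEFAULT_B",
    "CORE_TYPES",
    "RegulatoryGene",
    "BindingSite",
    "HouseholdGene",
    "Bead",
    "Genome",
    "GenomeStats",
    "GenomeParseError",
    "parse_genome",
    "serialize_genome",
    "random_bits",
]

#: Default binding-sequence length (bits).
DEFAULT_B = 20

#: The five core gene types g1..g5 whose joint expression defines the stage.
CORE_TYPES = (1, 2, 3, 4, 5)

#: Bounds for the regulatory weight and the activation threshold.
WEIGHT_RANGE = (-3, 3)
THRESHOLD_RANGE = (-2, 5)

Bits = tuple[int, ...]


def _check_bits(bits: Sequence[int], n: int | None, what: str) -> Bits:
    t = tuple(int(b) for b in bits)
    if any(b not in (0, 1) for b in t):
        raise ValueError(f"{what} must contain only 0/1 bits, got {t!r}")
    if n is not None and len(t) != n:
        raise ValueError(f"{what} must have length {n}, got {len(t)}")
    return t


def random_bits(rng, n: int) -> Bits:
    """Uniform random bit vector of length ``n``."""
    return tuple(int(b) for b in rng.integers(0, 2, size=n))


@dataclass(frozen=True)
class RegulatoryGene:
    """A regulatory gene bead.

    Parameters
    ----------
    type_id : int
        Small integer label; 1--5 are the core cell-cycle types g1--g5,
        larger ids label evolved, non-core types.
    binding_seq : tuple of int
        Bit vector of length B; products carry this sequence and bind sites
        by bit similarity.
    signal_peptide : tuple of int
        Two bits (host-bit, symbiont-bit): ``10`` host localization, ``01``
        symbiont localization, ``00`` no relocation, ``11`` dual.
    weight : int
        Signed regulatory effect exerted by the bound product.
    threshold : int
        Activation threshold the summed weights in the regulatory region
        must reach for expression.
    """

    type_id: int
    binding_seq: Bits
    signal_peptide: Bits
    weight: int
    threshold: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "binding_seq", _check_bits(self.binding_seq, None, "binding_seq"))
        object.__setattr__(
            self, "signal_peptide", _check_bits(self.signal_peptide, 2, "signal_peptide")
        )
        if self.type_id < 1:
            raise ValueError(f"type_id must be >= 1, got {self.type_id}")


@dataclass(frozen=True)
class BindingSite:
    """A binding-site bead: a bare bit vector of length B."""

    seq: Bits

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _check_bits(self.seq, None, "seq"))


@dataclass(frozen=True)
class HouseholdGene:
    """A passive household bead; counts toward L, never regulates."""


Bead = Union[RegulatoryGene, BindingSite, HouseholdGene]


@dataclass(frozen=True)
class GenomeStats:
    L: int
    R: int
    household_count: int
    gene_count: int
    site_count: int
    genes_per_type: dict[int, int]


class Genome:
    """An ordered, immutable-by-convention list of beads.

    Positions are 0-based; "upstream" of position *i* means positions
    ``< i``; replication proceeds from position 0 toward ``L - 1``.
    """

    __slots__ = ("beads", "B", "_hash", "_gene_pos", "_site_pos", "_kin", "_routing")

    def __init__(self, beads: Iterable[Bead] = (), B: int = DEFAULT_B):
        self.beads: tuple[Bead, ...] = tuple(beads)
        self.B = int(B)
        self._hash: int | None = None
        self._gene_pos: list[int] | None = None
        self._site_pos: list[int] | None = None
        self._kin: dict | None = None  # per-instance kinetics cache
        self._routing: bool | None = None
        for i, b in enumerate(self.beads):
            if isinstance(b, RegulatoryGene) and len(b.binding_seq) != self.B:
                raise ValueError(f"bead {i}: gene binding_seq length {len(b.binding_seq)} != B={self.B}")
            if isinstance(b, BindingSite) and len(b.seq) != self.B:
                raise ValueError(f"bead {i}: site seq length {len(b.seq)} != B={self.B}")

    # -- size statistics ---------------------------------------------------
    @property
    def L(self) -> int:
        return len(self.beads)

    @property
    def household_count(self) -> int:
        return sum(1 for b in self.beads if isinstance(b, HouseholdGene))

    @property
    def R(self) -> int:
        return self.L - self.household_count

    def __len__(self) -> int:
        return len(self.beads)

    def __iter__(self) -> Iterator[Bead]:
        return iter(self.beads)

    def __getitem__(self, i):
        return self.beads[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.B == other.B and self.beads == other.beads

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self.B, self.beads))
        return self._hash

    def __repr__(self) -> str:
        return f"<Genome L={self.L} R={self.R} B={self.B}>"

    # -- structural queries ------------------------------------------------
    def gene_positions(self) -> list[int]:
        if self._gene_pos is None:
            self._gene_pos = [
                i for i, b in enumerate(self.beads) if isinstance(b, RegulatoryGene)
            ]
        return self._gene_pos

    def site_positions(self) -> list[int]:
        if self._site_pos is None:
            self._site_pos = [
                i for i, b in enumerate(self.beads) if isinstance(b, BindingSite)
            ]
        return self._site_pos

    def has_routing_peptides(self) -> bool:
        """Whether any gene carries a non-00 signal peptide (cached)."""
        if self._routing is None:
            self._routing = any(
                self.beads[i].signal_peptide != (0, 0) for i in self.gene_positions()
            )
        return self._routing

    def regulatory_region(self, gene_index: int) -> list[int]:
        """Positions of the maximal contiguous run of binding sites
        immediately upstream of the gene at ``gene_index``.

        The run is terminated by any gene bead (regulatory or household)
        or by the genome start; a household bead therefore breaks a region.
        """
        if not (0 <= gene_index < self.L) or not isinstance(self.beads[gene_index], RegulatoryGene):
            raise ValueError(f"position {gene_index} is not a regulatory gene")
        region: list[int] = []
        i = gene_index - 1
        while i >= 0 and isinstance(self.beads[i], BindingSite):
            region.append(i)
            i -= 1
        region.reverse()
        return region

    def stats(self) -> GenomeStats:
        per_type: dict[int, int] = {}
        genes = sites = household = 0
        for b in self.beads:
            if isinstance(b, RegulatoryGene):
                genes += 1
                per_type[b.type_id] = per_type.get(b.type_id, 0) + 1
            elif isinstance(b, BindingSite):
                sites += 1
            else:
                household += 1
        return GenomeStats(
            L=self.L,
            R=genes + sites,
            household_count=household,
            gene_count=genes,
            site_count=sites,
            genes_per_type=per_type,
        )


# -- text serialization ----------------------------------------------------

class GenomeParseError(ValueError):
    """Raised on malformed genome-format input; message names the line."""


def _bits_str(bits: Bits) -> str:
    return "".join(str(b) for b in bits)


def serialize_genome(genome: Genome) -> str:
    """Render a genome in the v1 line-based format (canonical form)."""
    lines = [f"#endocycle-genome v1 B={genome.B}"]
    for b in genome.beads:
        if isinstance(b, HouseholdGene):
            lines.append("H")
        elif isinstance(b, BindingSite):
            lines.append(f"B\t{_bits_str(b.seq)}")
        else:
            lines.append(
                "G\t{}\t{}\t{}\t{}\t{}".format(
                    b.type_id,
                    _bits_str(b.binding_seq),
                    _bits_str(b.signal_peptide),
                    b.weight,
                    b.threshold,
                )
            )
    return "\n".join(lines) + "\n"


def _parse_bits(s: str, n: int | None, lineno: int, what: str) -> Bits:
    if not s or any(c not in "01" for c in s):
        raise GenomeParseError(f"line {lineno}: {what} must be a 0/1 string, got {s!r}")
    if n is not None and len(s) != n:
        raise GenomeParseError(f"line {lineno}: {what} has length {len(s)}, expected {n}")
    return tuple(int(c) for c in s)


def parse_genome(text: str, B: int | None = None) -> Genome:
    """Parse the v1 genome text format.

    One bead per line, tab- or whitespace-separated fields: ``H``
    (household); ``B <bits>`` (binding site); ``G <type_id> <bits>
    <sp-2bits> <weight> <threshold>`` (regulatory gene). A header line
    ``#endocycle-genome v1 B=<int>`` fixes the bit-vector length; other
    ``#`` lines and blank lines are ignored. ``B`` passed as an argument
    overrides a missing header.
    """
    beads: list[Bead] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#endocycle-genome"):
                for tok in line.split():
                    if tok.startswith("B="):
                        try:
                            B = int(tok[2:])
                        except ValueError:
                            raise GenomeParseError(f"line {lineno}: bad B= value in header") from None
            continue
        fields = line.split()
        kind = fields[0]
        if kind == "H":
            if len(fields) != 1:
                raise GenomeParseError(f"line {lineno}: household bead takes no fields")
            beads.append(HouseholdGene())
        elif kind == "B":
            if len(fields) != 2:
                raise GenomeParseError(f"line {lineno}: binding site needs exactly one bit string")
            beads.append(BindingSite(_parse_bits(fields[1], B, lineno, "site sequence")))
        elif kind == "G":
            if len(fields) != 6:
                raise GenomeParseError(f"line {lineno}: gene needs 5 fields, got {len(fields) - 1}")
            try:
                type_id = int(fields[1])
                weight = int(fields[4])
                threshold = int(fields[5])
            except ValueError:
                raise GenomeParseError(f"line {lineno}: non-integer gene field") from None
            beads.append(
                RegulatoryGene(
                    type_id=type_id,
                    binding_seq=_parse_bits(fields[2], B, lineno, "gene sequence"),
                    signal_peptide=_parse_bits(fields[3], 2, lineno, "signal peptide"),
                    weight=weight,
                    threshold=threshold,
                )
            )
        else:
            raise GenomeParseError(f"line {lineno}: unknown bead kind {kind!r}")
    if B is None:
        # infer from content; an empty genome defaults to DEFAULT_B
        for b in beads:
            if isinstance(b, BindingSite):
                B = len(b.seq)
                break
            if isinstance(b, RegulatoryGene):
                B = len(b.binding_seq)
                break
        else:
            B = DEFAULT_B
    return Genome(beads, B=B)
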