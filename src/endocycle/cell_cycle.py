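"""Single-cell cell-cycle state machine.

A cell steps through the stages G1 -> S -> G2 -> M, decoded each timestep
from the Boolean expression of its five core gene types. Progression is
checkpoint-like: a decoded pattern only advances the stage when it is the
exact successor of the last stage passed this cycle; any other pattern
stalls the cell (expression keeps evolving, the stage does not). Decoding
the M pattern is special: a cell that shows M without having passed
G1, S and G2 in order, or before its replication fork has reached the end
of the genome, dies on the spot. A legitimate M makes the cell
divided-ready; division itself (genome mutation, symbiont partitioning,
placement) is handled by the caller.

Replication happens only while the stage is S: the fork advances by up to
``k`` beads per timestep, where ``k`` is set by nutrient availability.
Genes behind the fork are present in two copies, which doubles their
product's binding affinity -- the dosage signal evolved replication
checkpoints feed on.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .genome import Genome, RegulatoryGene
from .regulation import (
    DEFAULT_AFFINITY_C,
    DEFAULT_AFFINITY_S,
    Localization,
    Origin,
    Product,
    ProductPool,
    Stage,
    StageTable,
    core_pattern,
    decode_stage,
    sample_occupancy,
    update_expression,
)

__all__ = [
    "CellEvent",
    "Cell",
    "CycleMetrics",
    "step_cell",
    "divide_cell",
    "minimal_cycle_time",
    "efficiency",
    "viability_check",
    "ViabilityResult",
]

STAGE_ORDER = (Stage.G1, Stage.S, Stage.G2, Stage.M)


class CellEvent(enum.Enum):
    NONE = "none"
    DIVIDED_READY = "divided-ready"
    DIED = "died"


@dataclass
class Cell:
    """A host or symbiont cell.

    ``fork`` counts beads replicated (0..L); bead *i* is replicated iff
    ``i < fork``. ``passed`` records stages completed since the last
    division, in order. ``foreign_pool`` holds leaked/targeted products
    delivered this timestep; it is cleared at the end of every step.
    """

    genome: Genome
    origin: Origin
    expression: tuple[bool, ...] = ()
    stage: Stage = Stage.G1
    passed: tuple[Stage, ...] = ()
    fork: int = 0
    foreign_pool: ProductPool = field(default_factory=ProductPool)
    alive: bool = True
    divided_ready: bool = False
    cell_id: int = 0

    def __post_init__(self) -> None:
        n = len(self.genome.gene_positions())
        if len(self.expression) != n:
            self.expression = tuple([False] * n)

    def raw_products(self) -> list[tuple[tuple[int, int], Product]]:
        """(signal peptide, product) of every expressed gene, ignoring
        routing; genes behind the fork carry a doubled copy number."""
        out: list[tuple[tuple[int, int], Product]] = []
        for expr, gi in zip(self.expression, self.genome.gene_positions()):
            if not expr:
                continue
            gene: RegulatoryGene = self.genome[gi]
            copies = 2 if gi < self.fork else 1
            out.append(
                (
                    gene.signal_peptide,
                    Product(
                        origin=self.origin,
                        type_id=gene.type_id,
                        seq=gene.binding_seq,
                        weight=gene.weight,
                        copies=copies,
                        localization=Localization.NATIVE,
                    ),
                )
            )
        return out

    def native_products(self) -> list[Product]:
        """Products present in this cell's own compartment: expressed
        genes whose signal peptide does not route them exclusively to the
        partner compartment."""
        from .regulation import stays_native

        return [p for sp, p in self.raw_products() if stays_native(self.origin, sp)]

    def expressed_genes(self) -> list[RegulatoryGene]:
        return [
            self.genome[gi]
            for expr, gi in zip(self.expression, self.genome.gene_positions())
            if expr
        ]


def _all_native(cell: Cell) -> bool:
    """True when every expressed gene's product stays in this cell."""
    from .regulation import stays_native

    for expr, gi in zip(cell.expression, cell.genome.gene_positions()):
        if expr:
            sp = cell.genome[gi].signal_peptide
            if sp != (0, 0) and not stays_native(cell.origin, sp):
                return False
    return True


def _next_expected(passed: tuple[Stage, ...]) -> Stage:
    return STAGE_ORDER[len(passed)] if len(passed) < 4 else Stage.M


def step_cell(
    cell: Cell,
    k: int,
    rng,
    table: StageTable,
    affinity_c: float = DEFAULT_AFFINITY_C,
    affinity_s: float = DEFAULT_AFFINITY_S,
) -> CellEvent:
    """Advance one cell by one timestep; returns the step's event.

    A divided-ready cell is frozen (it retries division through the
    caller) and a dead cell is inert.
    """
    if not cell.alive:
        return CellEvent.DIED
    if cell.divided_ready:
        cell.foreign_pool = ProductPool()
        return CellEvent.DIVIDED_READY

    from ._kinetics import compile_kinetics

    kin = compile_kinetics(cell.genome, affinity_c, affinity_s)
    if not cell.foreign_pool and (not kin.any_routing or _all_native(cell)):
        # no foreign products, no products routed away: compiled path
        expressed = [i for i, e in enumerate(cell.expression) if e]
        copies = [2 if kin.gene_positions[i] < cell.fork else 1 for i in expressed]
        cell.expression, bits = kin.step_expression(expressed, copies, rng)
    else:
        pool = ProductPool(cell.native_products())
        pool.extend(cell.foreign_pool)
        occupancy = sample_occupancy(cell.genome, pool, rng, c=affinity_c, s=affinity_s)
        cell.expression = update_expression(cell.genome, occupancy)
        bits = core_pattern(cell.expression, cell.genome, pool)
    decoded = decode_stage(bits, table)

    event = CellEvent.NONE
    if decoded is not None:
        expected = _next_expected(cell.passed)
        if decoded is Stage.M:
            if cell.passed == (Stage.G1, Stage.S, Stage.G2) and cell.fork >= cell.genome.L:
                cell.stage = Stage.M
                cell.passed = cell.passed + (Stage.M,)
                cell.divided_ready = True
                event = CellEvent.DIVIDED_READY
            else:
                cell.alive = False
                event = CellEvent.DIED
        elif decoded is expected:
            cell.stage = decoded
            cell.passed = cell.passed + (decoded,)
        # any other decoded stage stalls

    if cell.alive and cell.stage is Stage.S:
        cell.fork += min(k, cell.genome.L - cell.fork)

    cell.foreign_pool = ProductPool()
    return event


def divide_cell(
    cell: Cell,
    mutator: Optional[Callable[[Genome], Genome]],
    rng,
) -> tuple[Cell, Cell]:
    """Split a divided-ready cell into two daughters.

    Each daughter receives an independently mutated copy of the genome
    (``mutator`` is called once per daughter; pass None for no mutation),
    a reset fork and stage history, and the parent's expression state.
    """
    if not cell.divided_ready:
        raise ValueError("divide_cell called on a cell that is not divided-ready")

    def daughter() -> Cell:
        g = mutator(cell.genome) if mutator is not None else cell.genome
        n = len(g.gene_positions())
        expr = cell.expression
        if len(expr) != n:  # structural mutation changed gene count
            expr = tuple(list(expr)[:n] + [False] * (n - len(expr)))
        return Cell(
            genome=g,
            origin=cell.origin,
            expression=expr,
            stage=Stage.G1,
            passed=(),
            fork=0,
            foreign_pool=ProductPool(),
        )

    return daughter(), daughter()


@dataclass(frozen=True)
class CycleMetrics:
    """Observed vs minimal cycle duration for a genome size and nutrient level."""

    tau: float
    tau_min: float

    @property
    def e(self) -> float:
        return self.tau_min / self.tau


def minimal_cycle_time(L: int, k: int) -> int:
    """Fastest possible cycle: one step each for G1, G2 and M plus
    ``ceil(L/k)`` steps of S-phase replication."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return math.ceil(L / k) + 3


def efficiency(tau_min: float, tau: float) -> float:
    """Cell-cycle efficiency e = tau_min / tau, in (0, 1]."""
    if tau < tau_min:
        raise ValueError(f"observed tau={tau} below tau_min={tau_min}")
    return tau_min / tau


@dataclass(frozen=True)
class ViabilityResult:
    passed: bool
    divisions: int
    died: bool
    mean_tau: Optional[float]


def viability_check(
    genome: Genome,
    n_influx: float,
    T: int = 2000,
    rng=None,
    table: Optional[StageTable] = None,
    rho: float = 5.0,
    min_divisions: int = 5,
    origin: Origin = Origin.HOST,
) -> ViabilityResult:
    """Run one isolated cell (no leakage, no foreign products) for T steps.

    The replication budget is fixed at ``k = max(1, floor(n_influx / rho))``
    as for a lone cell taking the whole local nutrient influx. On each
    division one daughter is kept (no mutation). Passes iff the cell never
    dies and completes at least ``min_divisions`` divisions.
    """
    import numpy as np

    if rng is None:
        rng = np.random.default_rng(0)
    if table is None:
        table = StageTable()
    k = max(1, int(n_influx // rho))
    cell = Cell(genome=genome, origin=origin)
    divisions = 0
    taus: list[int] = []
    born_at = 0
    for t in range(1, T + 1):
        event = step_cell(cell, k, rng, table)
        if event is CellEvent.DIED:
            return ViabilityResult(False, divisions, True, _mean(taus))
        if event is CellEvent.DIVIDED_READY:
            d1, _ = divide_cell(cell, None, rng)
            cell = d1
            divisions += 1
            taus.append(t - born_at)
            born_at = t
    return ViabilityResult(divisions >= min_divisions, divisions, False, _mean(taus))


def _mean(xs) -> Optional[float]:
    return sum(xs) / len(xs) if xs else None


def trace_cell(
    genome: Genome,
    k: int,
    T: int,
    rng,
    table: Optional[StageTable] = None,
    origin: Origin = Origin.HOST,
    divide: bool = True,
) -> list[dict]:
    """Per-timestep trajectory log of one isolated cell.

    Returns one record per step: timestep, stage, fork (replication
    progress), expressed-gene count, and the step's event. With
    ``divide`` the cell is replaced by one unmutated daughter on each
    division (the log notes the event), mirroring the viability run.
    """
    if table is None:
        table = StageTable()
    cell = Cell(genome=genome, origin=origin)
    rows: list[dict] = []
    for t in range(1, T + 1):
        event = step_cell(cell, k, rng, table)
        rows.append(
            {
                "timestep": t,
                "stage": cell.stage.name,
                "fork": cell.fork,
                "expressed": sum(cell.expression),
                "event": event.value,
            }
        )
        if event is CellEvent.DIED:
            break
        if divide and event is CellEvent.DIVIDED_READY:
            cell, _ = divide_cell(cell, None, rng)
    return rows


def write_trace_tsv(fh, rows: list[dict]) -> None:
    fh.write("timestep\tstage\tfork\texpressed\tevent\n")
    for r in rows:
        fh.write(
            f"{r['timestep']}\t{r['stage']}\t{r['fork']}\t{r['expressed']}\t{r['event']}\n"
        )
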