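"""Spatial holobiont ecology on a nutrient gradient.

Holobionts (one host plus one or more symbionts) occupy at most one site
each on a grid that is toroidal in width and bounded in height. A
time-constant nutrient influx is arranged in horizontal bands
("sectors"), by default 11 sectors linearly spaced from 10 (top) to 110
(bottom). All cells of all holobionts in a site's 3x3 Moore neighborhood
share the local influx equally:

    A = influx(site) / C,     k = max(1, floor(A / rho))

where C is the neighborhood cell count and ``k`` is the number of beads a
cell in S-phase replicates per timestep (rho defaults to 5 beads per
nutrient unit). Crowding and high symbiont loads therefore slow
replication, the central ecological feedback of the model.

One synchronous timestep: nutrient shares are computed from the current
occupancy; signal-peptide targeting and then leakage fill the foreign
product pools; every cell steps; symbiont divisions add a symbiont in
place; a host division splits the holobiont into a random empty Moore
neighbor (stalling in divided-ready if there is none), partitioning the
symbionts binomially -- a daughter drawing zero symbionts is dead on
arrival; finally deaths are applied (premature-M, symbiont loss, and a
basal holobiont death probability delta per step) and all events are
appended to the lineage log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .cell_cycle import Cell, CellEvent, divide_cell, step_cell
from .genome import Genome
from .interference import InterferenceConfig, apply_leakage, apply_targeting, gene_transfer
from .mutation import MutationRates, Mutator
from .regulation import Origin, StageTable

__all__ = [
    "NutrientField",
    "Holobiont",
    "Grid",
    "Event",
    "Population",
    "nutrient_share",
    "divide_holobiont",
    "step_population",
    "population_summary",
]

DEFAULT_RHO = 5.0
DEFAULT_DELTA = 0.002


@dataclass(frozen=True)
class NutrientField:
    """Time-constant per-site nutrient influx in horizontal sector bands."""

    height: int = 110
    sectors: int = 11
    influx_min: float = 10.0
    influx_max: float = 110.0

    def __post_init__(self) -> None:
        if self.height % self.sectors != 0:
            raise ValueError(
                f"grid height {self.height} not divisible by {self.sectors} sectors"
            )
        object.__setattr__(
            self,
            "_sector_values",
            tuple(float(v) for v in np.linspace(self.influx_min, self.influx_max, self.sectors)),
        )
        object.__setattr__(self, "_rows_per_sector", self.height // self.sectors)

    @property
    def sector_values(self) -> tuple[float, ...]:
        return self._sector_values

    def sector_of_row(self, y: int) -> int:
        return y // self._rows_per_sector

    def influx(self, site: tuple[int, int]) -> float:
        return self.sector_values[self.sector_of_row(site[1])]

    @classmethod
    def uniform(cls, influx: float, height: int = 20) -> "NutrientField":
        """A single-sector field with the same influx everywhere, as used
        by the clonal growth assays."""
        return cls(height=height, sectors=1, influx_min=influx, influx_max=influx)


@dataclass
class Holobiont:
    host: Cell
    symbionts: list[Cell]
    site: tuple[int, int]
    hid: int = 0
    birth_symbiont_count: int = 1
    born_at: int = 0

    @property
    def n_cells(self) -> int:
        return 1 + len(self.symbionts)

    @property
    def alive(self) -> bool:
        return self.host.alive and len(self.symbionts) > 0


class Grid:
    """Occupancy map: at most one holobiont per site; toroidal in width,
    bounded in height."""

    def __init__(self, width: int = 45, height: int = 110):
        self.width = int(width)
        self.height = int(height)
        self.occupancy: dict[tuple[int, int], Holobiont] = {}

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    def place(self, h: Holobiont, site: tuple[int, int]) -> None:
        if site in self.occupancy:
            raise ValueError(f"site {site} already occupied")
        if not (0 <= site[0] < self.width and 0 <= site[1] < self.height):
            raise ValueError(f"site {site} off grid")
        self.occupancy[site] = h
        h.site = site

    def remove(self, site: tuple[int, int]) -> None:
        del self.occupancy[site]

    def neighborhood(self, site: tuple[int, int]) -> list[tuple[int, int]]:
        """The 3x3 Moore neighborhood including the site itself."""
        x, y = site
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                ny = y + dy
                if 0 <= ny < self.height:
                    out.append(((x + dx) % self.width, ny))
        return out

    def empty_neighbors(self, site: tuple[int, int]) -> list[tuple[int, int]]:
        return [s for s in self.neighborhood(site) if s != site and s not in self.occupancy]

    def holobionts(self) -> list[Holobiont]:
        return [self.occupancy[s] for s in sorted(self.occupancy)]


def nutrient_share(
    grid: Grid,
    fieldspec: NutrientField,
    site: tuple[int, int],
    rho: float = DEFAULT_RHO,
) -> tuple[float, int]:
    """Available nutrient A and beads-per-step budget k at an occupied site."""
    if site not in grid.occupancy:
        raise ValueError(f"site {site} not occupied")
    cells = sum(
        grid.occupancy[s].n_cells for s in grid.neighborhood(site) if s in grid.occupancy
    )
    A = fieldspec.influx(site) / cells
    k = max(1, int(A // rho))
    return A, k


@dataclass(frozen=True)
class Event:
    step: int
    kind: str  # birth | death | symbiont-birth | symbiont-death | transfer
    site: tuple[int, int]
    parent_id: int
    child_id: int
    detail: str = ""


class Population:
    """A running simulation: grid, nutrient field, parameters, rng streams
    and the append-only event log.

    The master seed expands into named substreams (ecology, mutation,
    binding, assay) so that subsystems draw independently.
    """

    def __init__(
        self,
        grid: Grid,
        fieldspec: NutrientField,
        rates: MutationRates = MutationRates(),
        interference: InterferenceConfig = InterferenceConfig(),
        table: StageTable = StageTable(),
        rho: float = DEFAULT_RHO,
        delta: float = DEFAULT_DELTA,
        seed: int = 0,
    ):
        self.grid = grid
        self.field = fieldspec
        self.rates = rates
        self.interference = interference
        self.table = table
        self.rho = rho
        self.delta = delta
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        eco, mut, bind, assay = ss.spawn(4)
        self.rng_ecology = np.random.default_rng(eco)
        self.rng_binding = np.random.default_rng(bind)
        self.rng_assay = np.random.default_rng(assay)
        self.mutator = Mutator(rates, np.random.default_rng(mut))
        self.t = 0
        self.events: list[Event] = []
        self._next_hid = 1
        self._next_cid = 1
        self.birth_genomes: dict[int, tuple[Genome, ...]] = {}
        self.cell_parents: dict[int, int] = {}

    # -- inoculation -------------------------------------------------------
    def next_hid(self) -> int:
        v = self._next_hid
        self._next_hid += 1
        return v

    def next_cid(self) -> int:
        v = self._next_cid
        self._next_cid += 1
        return v

    def add_holobiont(
        self,
        host_genome: Genome,
        symbiont_genomes: Iterable[Genome],
        site: tuple[int, int],
        expression: tuple[bool, ...] | None = None,
    ) -> Holobiont:
        host = Cell(genome=host_genome, origin=Origin.HOST, cell_id=self.next_cid())
        symbionts = [
            Cell(genome=g, origin=Origin.SYMBIONT, cell_id=self.next_cid())
            for g in symbiont_genomes
        ]
        if expression is not None:
            host.expression = expression
            for s in symbionts:
                s.expression = expression
        h = Holobiont(
            host=host,
            symbionts=symbionts,
            site=site,
            hid=self.next_hid(),
            birth_symbiont_count=len(symbionts),
            born_at=self.t,
        )
        self.grid.place(h, site)
        self.birth_genomes[h.hid] = (host_genome,) + tuple(symbiont_genomes)
        self.events.append(Event(self.t, "birth", site, 0, h.hid, "inoculum"))
        return h

    # -- one synchronous timestep -----------------------------------------
    def step(self) -> None:
        self.t += 1
        rng = self.rng_ecology
        occupied = sorted(self.grid.occupancy)
        if not occupied:
            return
        budgets = {s: nutrient_share(self.grid, self.field, s, self.rho)[1] for s in occupied}

        for s in occupied:
            h = self.grid.occupancy[s]
            apply_targeting(h.host, h.symbionts, self.interference)
            apply_leakage(h.host, h.symbionts, self.interference, rng)

        order = [occupied[i] for i in rng.permutation(len(occupied))]
        for site in order:
            h = self.grid.occupancy.get(site)
            if h is None or not h.alive:
                continue
            k = budgets[site]
            self._step_holobiont(h, k, rng)

        # basal turnover and cleanup
        for site in list(self.grid.occupancy):
            h = self.grid.occupancy[site]
            basal = self.delta > 0 and rng.random() < self.delta
            if basal or not h.alive:
                why = "basal" if basal else ("host-death" if not h.host.alive else "no-symbionts")
                self.events.append(Event(self.t, "death", site, h.hid, 0, why))
                self.grid.remove(site)

    def _step_holobiont(self, h: Holobiont, k: int, rng) -> None:
        host_event = step_cell(h.host, k, rng, self.table)
        sym_events = [step_cell(s, k, rng, self.table) for s in h.symbionts]

        # symbiont divisions: daughter pair replaces the parent in place
        new_symbionts: list[Cell] = []
        divided_syms: list[Cell] = []
        for s, ev in zip(h.symbionts, sym_events):
            if ev is CellEvent.DIVIDED_READY and s.divided_ready:
                d1, d2 = divide_cell(s, self.mutator, rng)
                d1.cell_id, d2.cell_id = self.next_cid(), self.next_cid()
                self.cell_parents[d1.cell_id] = s.cell_id
                self.cell_parents[d2.cell_id] = s.cell_id
                new_symbionts.extend([d1, d2])
                divided_syms.extend([d1, d2])
                self.events.append(
                    Event(self.t, "symbiont-birth", h.site, h.hid, h.hid, f"cell={s.cell_id}")
                )
            elif s.alive:
                new_symbionts.append(s)
            else:
                self.events.append(
                    Event(self.t, "symbiont-death", h.site, h.hid, 0, f"cell={s.cell_id}")
                )
        h.symbionts = new_symbionts
        if divided_syms:
            n = gene_transfer(
                h.host, h.symbionts, self.interference, rng,
                just_divided_host=False, just_divided_symbionts=divided_syms,
            )
            if n:
                self.events.append(Event(self.t, "transfer", h.site, h.hid, h.hid, f"h->s x{n}"))

        if host_event is CellEvent.DIVIDED_READY and h.host.divided_ready and h.symbionts:
            empties = self.grid.empty_neighbors(h.site)
            if empties:
                target = empties[int(rng.integers(0, len(empties)))]
                self._divide_holobiont(h, target, rng)
            # else: stall in divided-ready, retry next step

    def _divide_holobiont(self, h: Holobiont, target: tuple[int, int], rng) -> None:
        d1, d2, n_transfers = divide_holobiont(
            h, rng, mutator=self.mutator, interference=self.interference,
            cid_source=self.next_cid, parents=self.cell_parents,
        )
        self.grid.remove(h.site)
        survivors = []
        for d, site in ((d1, h.site), (d2, target)):
            if d.symbionts:
                d.hid = self.next_hid()
                d.born_at = self.t
                self.grid.place(d, site)
                self.birth_genomes[d.hid] = (d.host.genome,) + tuple(
                    s.genome for s in d.symbionts
                )
                self.events.append(Event(self.t, "birth", site, h.hid, d.hid))
                survivors.append(d)
            else:
                self.events.append(Event(self.t, "death", site, h.hid, 0, "no-symbionts-at-birth"))
        if n_transfers:
            self.events.append(Event(self.t, "transfer", h.site, h.hid, h.hid, f"s->h x{n_transfers}"))

    def run(self, steps: int) -> None:
        for _ in range(steps):
            self.step()

    def summary(self) -> dict:
        return population_summary(self.grid, self.field)


def divide_holobiont(
    h: Holobiont,
    rng,
    mutator=None,
    interference: Optional[InterferenceConfig] = None,
    cid_source=None,
    parents: Optional[dict[int, int]] = None,
) -> tuple[Holobiont, Holobiont, int]:
    """Split a holobiont whose host is divided-ready.

    The host divides into two independently mutated daughters; each
    symbiont goes to daughter A or B with probability 1/2. A daughter
    with zero symbionts is dead on arrival (its ``symbionts`` list is
    empty; the caller discards it). Newly divided hosts then draw gene
    transfers from their symbionts. Returns (daughter_A, daughter_B,
    n_transfer_events).
    """
    if not h.host.divided_ready:
        raise ValueError("divide_holobiont: host is not divided-ready")
    host_a, host_b = divide_cell(h.host, mutator, rng)
    if cid_source is not None:
        host_a.cell_id, host_b.cell_id = cid_source(), cid_source()
        if parents is not None:
            parents[host_a.cell_id] = h.host.cell_id
            parents[host_b.cell_id] = h.host.cell_id
    syms_a: list[Cell] = []
    syms_b: list[Cell] = []
    for s in h.symbionts:
        (syms_a if rng.random() < 0.5 else syms_b).append(s)
    da = Holobiont(host=host_a, symbionts=syms_a, site=h.site,
                   birth_symbiont_count=len(syms_a), born_at=h.born_at)
    db = Holobiont(host=host_b, symbionts=syms_b, site=h.site,
                   birth_symbiont_count=len(syms_b), born_at=h.born_at)
    n = 0
    if interference is not None:
        for d in (da, db):
            if d.symbionts:
                n += gene_transfer(
                    d.host, d.symbionts, interference, rng, just_divided_host=True
                )
    return da, db, n


def step_population(pop: Population) -> list[Event]:
    """Advance one timestep and return the events it produced."""
    n0 = len(pop.events)
    pop.step()
    return pop.events[n0:]


def population_summary(grid: Grid, fieldspec: NutrientField) -> dict:
    """Occupancy and genome-size summaries, overall and per nutrient sector."""
    hs = grid.holobionts()
    n_sectors = fieldspec.sectors
    per_sector_occ = [0] * n_sectors
    per_sector_sites = [0] * n_sectors
    for y in range(grid.height):
        per_sector_sites[fieldspec.sector_of_row(y)] += grid.width
    host_L: list[list[int]] = [[] for _ in range(n_sectors)]
    host_R: list[list[int]] = [[] for _ in range(n_sectors)]
    sym_L: list[list[int]] = [[] for _ in range(n_sectors)]
    sym_R: list[list[int]] = [[] for _ in range(n_sectors)]
    for h in hs:
        sec = fieldspec.sector_of_row(h.site[1])
        per_sector_occ[sec] += 1
        host_L[sec].append(h.host.genome.L)
        host_R[sec].append(h.host.genome.R)
        for s in h.symbionts:
            sym_L[sec].append(s.genome.L)
            sym_R[sec].append(s.genome.R)

    def _mean(xs):
        return float(np.mean(xs)) if xs else None

    return {
        "N": len(hs) / grid.n_sites,
        "n_holobionts": len(hs),
        "per_sector_N": [
            occ / sites if sites else 0.0
            for occ, sites in zip(per_sector_occ, per_sector_sites)
        ],
        "host_L_per_sector": [_mean(xs) for xs in host_L],
        "host_R_per_sector": [_mean(xs) for xs in host_R],
        "symbiont_L_per_sector": [_mean(xs) for xs in sym_L],
        "symbiont_R_per_sector": [_mean(xs) for xs in sym_R],
        "mean_symbionts": _mean([len(h.symbionts) for h in hs]),
        "S_over_H": _mean([h.birth_symbiont_count for h in hs]),
    }
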