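"""Assay harness: clonal growth, interference knockouts, competition and
ancestor-lineage reconstruction.

Clonal assays grow a single holobiont genotype (mutation frozen, so the
measured density reflects the genotype alone) on a uniform-influx grid
and report the equilibrium occupied fraction N. Knockout panels repeat
the assay with individual interference channels disabled and report the
density change each knockout causes. Competition inoculates two
populations side by side and runs until fixation or a step budget.
Ancestry reconstruction walks the birth-event forest of a run back from
the individuals alive at its end to their most recent common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import Genome
from .interference import InterferenceConfig
from .mutation import MutationRates
from .population import Event, Grid, NutrientField, Population
from .regulation import StageTable

__all__ = [
    "AssayResult",
    "KnockoutResult",
    "CompetitionResult",
    "MRCAResult",
    "clonal_growth_assay",
    "KNOCKOUT_TOGGLES",
    "knockout_panel",
    "competition",
    "reconstruct_ancestry",
    "mrca_of",
    "lineage_to_newick",
]


@dataclass(frozen=True)
class AssayResult:
    N_equilibrium: float
    toggles: dict
    delta_N: Optional[float] = None
    trajectory: tuple[float, ...] = ()


def _seed_clonal_grid(
    pop: Population,
    host_genome: Genome,
    symbiont_genome: Genome,
    rng,
    fill: float = 0.1,
    symbionts_per_holobiont: int = 2,
) -> None:
    sites = [(x, y) for x in range(pop.grid.width) for y in range(pop.grid.height)]
    n = max(1, int(fill * len(sites)))
    chosen = [sites[i] for i in rng.choice(len(sites), size=n, replace=False)]
    for s in chosen:
        pop.add_holobiont(host_genome, [symbiont_genome] * symbionts_per_holobiont, s)


def clonal_growth_assay(
    host_genome: Genome,
    symbiont_genome: Genome,
    n_influx: float,
    toggles: Optional[InterferenceConfig] = None,
    T: int = 5000,
    window: Optional[int] = None,
    seed: int = 0,
    grid_size: tuple[int, int] = (20, 20),
    table: Optional[StageTable] = None,
    delta: float = 0.002,
    rho: float = 5.0,
    fill: float = 0.1,
) -> AssayResult:
    """Equilibrium grid density N of one clonal holobiont type.

    A uniform-influx grid is seeded with identical holobionts (two
    symbionts each), mutation rates are forced to zero, and the
    population runs T steps under the given interference toggles.
    N_equilibrium is the mean occupied fraction over the final ``window``
    steps (default: the last 20% of T). A nonviable clone simply reports
    N = 0.
    """
    if toggles is None:
        toggles = InterferenceConfig()
    if window is None:
        window = max(1, T // 5)
    if window > T:
        raise ValueError("window exceeds T")
    w, h = grid_size
    pop = Population(
        Grid(w, h),
        NutrientField.uniform(n_influx, height=h),
        rates=MutationRates.zero(),
        interference=replace(toggles, transfer_rate=0.0, transfer_enabled=False),
        table=table if table is not None else StageTable(),
        delta=delta,
        rho=rho,
        seed=seed,
    )
    _seed_clonal_grid(pop, host_genome, symbiont_genome, pop.rng_assay, fill=fill)
    traj: list[float] = []
    for t in range(T):
        pop.step()
        if t >= T - window:
            traj.append(len(pop.grid.occupancy) / pop.grid.n_sites)
        if not pop.grid.occupancy and t < T - window:
            # extinct before the window: N over the window is exactly 0
            traj = [0.0] * window
            break
    return AssayResult(
        N_equilibrium=float(np.mean(traj)) if traj else 0.0,
        toggles={
            "leakage_h_to_s": toggles.leakage_host_to_symbiont and toggles.leakage_rate > 0,
            "leakage_s_to_h": toggles.leakage_symbiont_to_host and toggles.leakage_rate > 0,
            "targeting_h_to_s": toggles.targeting_host_to_symbiont,
            "targeting_s_to_h": toggles.targeting_symbiont_to_host,
        },
        trajectory=tuple(traj),
    )


#: The knockout panel: name -> field overrides relative to baseline.
KNOCKOUT_TOGGLES: dict[str, dict] = {
    "baseline": {},
    "no_leakage_h_to_s": {"leakage_host_to_symbiont": False},
    "no_leakage_s_to_h": {"leakage_symbiont_to_host": False},
    "no_leakage_both": {"leakage_host_to_symbiont": False, "leakage_symbiont_to_host": False},
    "no_targeting_h_to_s": {"targeting_host_to_symbiont": False},
    "no_targeting_s_to_h": {"targeting_symbiont_to_host": False},
    "no_targeting_both": {"targeting_host_to_symbiont": False, "targeting_symbiont_to_host": False},
}


@dataclass(frozen=True)
class KnockoutResult:
    baseline_N: float
    delta_N: dict[str, float]
    se: dict[str, float]
    per_seed: dict[str, tuple[float, ...]]


def knockout_panel(
    host_genome: Genome,
    symbiont_genome: Genome,
    n_influx: float,
    T: int = 5000,
    seeds: Sequence[int] = (0, 1, 2),
    baseline: Optional[InterferenceConfig] = None,
    **assay_kwargs,
) -> KnockoutResult:
    """Density change caused by disabling each interference channel.

    Runs the clonal assay for the baseline and each knockout over several
    seeds; reports mean delta_N = N(knockout) - N(baseline) per toggle
    with its Monte-Carlo standard error.
    """
    if baseline is None:
        baseline = InterferenceConfig()
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    runs: dict[str, list[float]] = {name: [] for name in KNOCKOUT_TOGGLES}
    for seed in seeds:
        for name, overrides in KNOCKOUT_TOGGLES.items():
            cfg = replace(baseline, **overrides)
            res = clonal_growth_assay(
                host_genome, symbiont_genome, n_influx,
                toggles=cfg, T=T, seed=seed, **assay_kwargs,
            )
            runs[name].append(res.N_equilibrium)
    base = np.asarray(runs["baseline"], dtype=float)
    delta: dict[str, float] = {}
    se: dict[str, float] = {}
    for name in KNOCKOUT_TOGGLES:
        if name == "baseline":
            continue
        d = np.asarray(runs[name], dtype=float) - base
        delta[name] = float(d.mean())
        se[name] = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else float("nan")
    return KnockoutResult(
        baseline_N=float(base.mean()),
        delta_N=delta,
        se=se,
        per_seed={k: tuple(v) for k, v in runs.items()},
    )


@dataclass(frozen=True)
class CompetitionResult:
    winner: Optional[str]  # "A", "B" or None for coexistence at T
    final_density: dict[str, float]
    densities: tuple[tuple[float, float], ...]  # per sampled step (A, B)
    stopped_at: int


def competition(
    pop_A: Sequence[tuple[Genome, Sequence[Genome]]],
    pop_B: Sequence[tuple[Genome, Sequence[Genome]]],
    T: int = 100_000,
    seed: int = 0,
    grid: Optional[Grid] = None,
    fieldspec: Optional[NutrientField] = None,
    interference: Optional[InterferenceConfig] = None,
    table: Optional[StageTable] = None,
    delta: float = 0.002,
    rho: float = 5.0,
    fill: float = 0.2,
    sample_every: int = 10,
) -> CompetitionResult:
    """Compete two saved populations side by side until fixation or T.

    ``pop_A``/``pop_B`` are sequences of (host genome, symbiont genomes)
    holobiont seeds. The left half of the grid is inoculated from A and
    the right half from B, subsampled to equal initial densities; the run
    uses no mutation so lineage labels stay meaningful, and halts the
    step one side's density reaches zero.
    """
    if not pop_A or not pop_B:
        raise ValueError("both populations must be nonempty")
    if grid is None:
        grid = Grid(30, 20)
    if fieldspec is None:
        fieldspec = NutrientField.uniform(90.0, height=grid.height)
    pop = Population(
        grid, fieldspec,
        rates=MutationRates.zero(),
        interference=interference if interference is not None else InterferenceConfig.all_off(),
        table=table if table is not None else StageTable(),
        delta=delta, rho=rho, seed=seed,
    )
    rng = pop.rng_assay
    half = grid.width // 2
    n_each = max(1, int(fill * half * grid.height))
    n_each = min(n_each, len(pop_A) * half * grid.height, len(pop_B) * half * grid.height)
    label: dict[int, str] = {}

    def _inoculate(source, xs, tag):
        sites = [(x, y) for x in xs for y in range(grid.height)]
        idx = rng.choice(len(sites), size=n_each, replace=False)
        for i in idx:
            hgen, sgens = source[int(rng.integers(0, len(source)))]
            h = pop.add_holobiont(hgen, list(sgens), sites[int(i)])
            label[h.hid] = tag

    _inoculate(pop_A, range(half), "A")
    _inoculate(pop_B, range(half, grid.width), "B")

    densities: list[tuple[float, float]] = []
    stopped_at = T
    for t in range(1, T + 1):
        n0 = len(pop.events)
        pop.step()
        for e in pop.events[n0:]:
            if e.kind == "birth" and e.parent_id in label:
                label[e.child_id] = label[e.parent_id]
        counts = {"A": 0, "B": 0}
        for h in pop.grid.occupancy.values():
            counts[label[h.hid]] += 1
        if t % sample_every == 0 or counts["A"] == 0 or counts["B"] == 0:
            densities.append(
                (counts["A"] / grid.n_sites, counts["B"] / grid.n_sites)
            )
        if counts["A"] == 0 or counts["B"] == 0:
            stopped_at = t
            break
    dA, dB = densities[-1] if densities else (0.0, 0.0)
    winner = None
    if dA == 0.0 and dB > 0.0:
        winner = "B"
    elif dB == 0.0 and dA > 0.0:
        winner = "A"
    return CompetitionResult(
        winner=winner,
        final_density={"A": dA, "B": dB},
        densities=tuple(densities),
        stopped_at=stopped_at,
    )


# -- ancestry ---------------------------------------------------------------

@dataclass(frozen=True)
class MRCAResult:
    mrca: Optional[int]
    path_to_root: tuple[int, ...]  # root .. mrca
    genomes: Optional[tuple[Genome, ...]]


def _root_path(node: int, parents: dict[int, int]) -> list[int]:
    path = [node]
    seen = {node}
    while path[-1] in parents:
        nxt = parents[path[-1]]
        if nxt in seen:
            raise ValueError(f"lineage cycle at record {nxt}")
        path.append(nxt)
        seen.add(nxt)
    path.reverse()
    return path


def mrca_of(leaves: Iterable[int], parents: dict[int, int]) -> Optional[int]:
    """Most recent common ancestor of ``leaves`` in a parent-pointer
    forest: the deepest node shared by every root path, or None when the
    leaves span different roots."""
    leaves = list(leaves)
    if not leaves:
        return None
    paths = [_root_path(n, parents) for n in leaves]
    mrca = None
    for depth, nodes in enumerate(zip(*paths)):
        if len(set(nodes)) == 1:
            mrca = nodes[0]
        else:
            break
    return mrca


def reconstruct_ancestry(pop: Population, genomes: bool = True) -> dict[str, MRCAResult]:
    """MRCA of the current population, for holobiont (host) lineages and
    for symbiont cell lineages separately.

    Holobiont ancestry comes from the birth events of the lineage log
    (one host per holobiont, so host and holobiont lineages coincide);
    symbiont ancestry from the per-cell parent map. Genomes are the
    snapshots recorded at each ancestor's birth.
    """
    parents: dict[int, int] = {}
    for e in pop.events:
        if e.kind == "birth" and e.parent_id != 0:
            if e.child_id in parents and parents[e.child_id] != e.parent_id:
                raise ValueError(f"conflicting parent records for holobiont {e.child_id}")
            parents[e.child_id] = e.parent_id
    alive = [h.hid for h in pop.grid.holobionts()]
    h_mrca = mrca_of(alive, parents)
    h_path = tuple(_root_path(h_mrca, parents)) if h_mrca is not None else ()
    h_genomes = None
    if genomes and h_mrca is not None:
        h_genomes = tuple(
            pop.birth_genomes[a][0] for a in h_path if a in pop.birth_genomes
        )

    sym_leaves = [s.cell_id for h in pop.grid.holobionts() for s in h.symbionts]
    s_mrca = mrca_of(sym_leaves, pop.cell_parents)
    s_path = tuple(_root_path(s_mrca, pop.cell_parents)) if s_mrca is not None else ()
    return {
        "holobiont": MRCAResult(h_mrca, h_path, h_genomes),
        "symbiont": MRCAResult(s_mrca, s_path, None),
    }


def lineage_to_newick(pop: Population) -> str:
    """The holobiont birth forest as a Newick string (one tree per
    inoculant root; branch lengths in timesteps)."""
    children: dict[int, list[int]] = {}
    birth_time: dict[int, int] = {}
    roots: list[int] = []
    for e in pop.events:
        if e.kind != "birth":
            continue
        birth_time[e.child_id] = e.step
        if e.parent_id == 0:
            roots.append(e.child_id)
        else:
            children.setdefault(e.parent_id, []).append(e.child_id)
    death_time = {
        e.parent_id: e.step for e in pop.events if e.kind == "death" and e.parent_id
    }
    t_now = pop.t

    def render(node: int) -> str:
        end = death_time.get(node, t_now)
        kids = children.get(node, [])
        length = max(0, end - birth_time.get(node, 0))
        if not kids:
            return f"h{node}:{length}"
        inner = ",".join(render(c) for c in kids)
        return f"({inner})h{node}:{length}"

    return "".join(f"{render(r)};\n" for r in roots)
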