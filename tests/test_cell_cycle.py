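"""Single-cell state machine: staged progression, replication, death rule."""

import numpy as np
import pytest

from endocycle.bootstrap import generate_bootstrap_genomes
from endocycle.cell_cycle import (
    Cell,
    CellEvent,
    divide_cell,
    efficiency,
    minimal_cycle_time,
    step_cell,
    viability_check,
)
from endocycle.fixtures import constitutive_m_genome, nonviable_genome
from endocycle.genome import BindingSite, Genome, RegulatoryGene
from endocycle.mutation import MutationRates, Mutator
from endocycle.regulation import (
    Localization,
    Origin,
    Product,
    ProductPool,
    Stage,
    StageTable,
)

from conftest import random_genome


class TestMinimalCycleTime:
    def test_formula(self):
        assert minimal_cycle_time(64, 8) == 11
        assert minimal_cycle_time(64, 18) == 7  # ceil(64/18)=4, +3

    def test_efficiency_bounds(self):
        assert efficiency(11, 11) == 1.0
        assert efficiency(11, 22) == 0.5
        with pytest.raises(ValueError, match="below tau_min"):
            efficiency(11, 10)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            minimal_cycle_time(64, 0)


class TestStepCell:
    def test_fork_clamps_at_genome_end(self, bootstrap_genome, stage_table, rng):
        cell = Cell(genome=bootstrap_genome, origin=Origin.HOST,
                    stage=Stage.S, passed=(Stage.G1, Stage.S), fork=60)
        step_cell(cell, 6, rng, stage_table)
        assert cell.fork == 64

    def test_premature_m_kills(self, stage_table, rng):
        cell = Cell(genome=constitutive_m_genome(), origin=Origin.HOST)
        events = [step_cell(cell, 18, rng, stage_table) for _ in range(5)]
        assert CellEvent.DIED in events
        assert not cell.alive

    def test_stall_on_non_successor(self, bootstrap_genome, stage_table, rng):
        # a genome with no expressed genes never matches the next pattern
        cell = Cell(genome=nonviable_genome(), origin=Origin.HOST)
        for _ in range(20):
            assert step_cell(cell, 18, rng, stage_table) is CellEvent.NONE
        assert cell.stage is Stage.G1 and cell.passed == ()

    def test_dosage_doubles_behind_fork(self, bootstrap_genome):
        cell = Cell(genome=bootstrap_genome, origin=Origin.HOST, fork=3)
        cell.expression = tuple(True for _ in bootstrap_genome.gene_positions())
        copies = {p.type_id: p.copies for _, p in cell.raw_products()}
        # gene g5 sits at position 0 (< fork): duplicated; g1 at 63: not
        assert copies[5] == 2
        assert copies[1] == 1

    def test_death_rule_never_divides_early(self, stage_table):
        """No divided-ready event ever occurs with fork < L or with an
        out-of-order stage history (randomized trajectories)."""
        rng = np.random.default_rng(99)
        host, _ = generate_bootstrap_genomes()
        violations = 0
        for trial in range(300):
            g = host if trial % 3 == 0 else random_genome(rng, n_beads=int(rng.integers(5, 40)))
            if g.L == 0:
                continue
            cell = Cell(genome=g, origin=Origin.HOST)
            k = int(rng.integers(1, 20))
            for _ in range(60):
                ev = step_cell(cell, k, rng, stage_table)
                if ev is CellEvent.DIVIDED_READY:
                    if cell.fork < g.L or cell.passed[:3] != (Stage.G1, Stage.S, Stage.G2):
                        violations += 1
                    break
                if ev is CellEvent.DIED:
                    break
        assert violations == 0


class TestDivideCell:
    def _ready_cell(self, genome):
        return Cell(genome=genome, origin=Origin.HOST, fork=genome.L,
                    passed=(Stage.G1, Stage.S, Stage.G2, Stage.M),
                    stage=Stage.M, divided_ready=True,
                    expression=tuple(True for _ in genome.gene_positions()))

    def test_requires_ready(self, bootstrap_genome, rng):
        with pytest.raises(ValueError, match="not divided-ready"):
            divide_cell(Cell(genome=bootstrap_genome, origin=Origin.HOST), None, rng)

    def test_zero_rates_give_identical_daughters(self, bootstrap_genome, rng):
        cell = self._ready_cell(bootstrap_genome)
        mut = Mutator(MutationRates.zero(), rng)
        d1, d2 = divide_cell(cell, mut, rng)
        assert d1.genome == d2.genome == bootstrap_genome

    def test_reset_contract(self, bootstrap_genome, rng):
        cell = self._ready_cell(bootstrap_genome)
        d1, d2 = divide_cell(cell, None, rng)
        for d in (d1, d2):
            assert d.fork == 0 and d.passed == () and d.stage is Stage.G1
            assert d.expression == cell.expression  # inherited
            assert not d.foreign_pool

    def test_daughters_mutate_independently(self, bootstrap_genome):
        """P(both daughters carry the same new mutation) scales as rate
        squared, not rate: daughters draw mutations separately."""
        rng = np.random.default_rng(17)
        rate = 4e-4  # ~0.1 change probability over the 280 sequence bits
        rates = MutationRates.zero().__class__(
            mu_B=rate, mu_S=0, mu_w=0, mu_theta=0,
            mu_dup=0, mu_del=0, mu_rel=0, mu_b_in=0, mu_r_in=0,
        )
        mut = Mutator(rates, rng)
        cell = self._ready_cell(bootstrap_genome)
        n = 2000
        one_changed = both_changed = 0
        for _ in range(n):
            d1, d2 = divide_cell(cell, mut, rng)
            c1 = d1.genome != bootstrap_genome
            c2 = d2.genome != bootstrap_genome
            one_changed += c1 + c2
            both_changed += c1 and c2
        p_change = one_changed / (2 * n)
        # independence: P(both) ~ p^2, far below p
        assert both_changed / n == pytest.approx(p_change**2, abs=4 * np.sqrt(p_change**2 / n) + 0.01)
        assert both_changed / n < p_change / 2


class TestViability:
    def test_bootstrap_passes_at_high_nutrients(self, bootstrap_genome):
        r = viability_check(bootstrap_genome, 90, T=2000, rng=np.random.default_rng(1))
        assert r.passed and r.divisions >= 5 and not r.died

    def test_gene_free_genome_fails_without_dying(self):
        r = viability_check(nonviable_genome(), 90, T=300, rng=np.random.default_rng(0))
        assert not r.passed and r.divisions == 0 and not r.died

    def test_constitutive_m_dies_fast(self):
        r = viability_check(constitutive_m_genome(), 90, T=300, rng=np.random.default_rng(0))
        assert r.died

    def test_efficiency_reproducible_across_seeds(self, bootstrap_genome):
        """e = tau_min/tau of the bootstrap circuit is small (checkpoint
        wait dominates) but stable across seeds."""
        es = []
        for seed in (1, 2, 3, 4):
            r = viability_check(bootstrap_genome, 90, T=2000, rng=np.random.default_rng(seed))
            assert r.divisions > 0
            es.append(minimal_cycle_time(64, 18) / r.mean_tau)
        assert max(es) - min(es) < 0.05


class TestTrace:
    def test_trajectory_log_tracks_replication(self, bootstrap_genome):
        import io as _io

        from endocycle.cell_cycle import trace_cell, write_trace_tsv

        rows = trace_cell(bootstrap_genome, k=18, T=400,
                          rng=np.random.default_rng(1))
        assert rows[0]["timestep"] == 1
        forks = [r["fork"] for r in rows]
        assert max(forks) == bootstrap_genome.L
        stages = {r["stage"] for r in rows}
        assert "S" in stages
        buf = _io.StringIO()
        write_trace_tsv(buf, rows)
        lines = buf.getvalue().splitlines()
        assert lines[0].startswith("timestep\t")
        assert len(lines) == len(rows) + 1


class TestFastPathEquivalence:
    def test_compiled_path_matches_object_path_distribution(self, bootstrap_genome, stage_table):
        """One step from a fixed state gives the same expression
        distribution through the compiled kernel as through the
        object-level route (which is forced by a foreign product of
        negligible affinity)."""
        far_seq = tuple([1, 0] * 10)
        spoiler = Product(Origin.SYMBIONT, 9, far_seq, 0, 1, Localization.LEAKED)
        start_expr = tuple(
            bootstrap_genome[gi].threshold <= 0
            for gi in bootstrap_genome.gene_positions()
        )
        n = 4000
        counts = {}
        for use_slow in (False, True):
            rng = np.random.default_rng(123)
            tally = {}
            for _ in range(n):
                cell = Cell(genome=bootstrap_genome, origin=Origin.HOST,
                            expression=start_expr)
                if use_slow:
                    cell.foreign_pool.add(spoiler)
                step_cell(cell, 18, rng, stage_table)
                tally[cell.expression] = tally.get(cell.expression, 0) + 1
            counts[use_slow] = tally
        keys = sorted(set(counts[False]) | set(counts[True]))
        for k in keys:
            p_fast = counts[False].get(k, 0) / n
            p_slow = counts[True].get(k, 0) / n
            se = np.sqrt(max(p_fast, p_slow, 1e-4) / n)
            assert abs(p_fast - p_slow) < 5 * se + 0.01
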