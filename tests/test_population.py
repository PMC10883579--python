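"""Spatial holobiont ecology: nutrient sharing, division, grid stepping."""

import numpy as np
import pytest
from scipy import stats as sps

from endocycle.bootstrap import generate_bootstrap_genomes
from endocycle.cell_cycle import Cell, Stage
from endocycle.fixtures import constitutive_m_genome, nonviable_genome
from endocycle.interference import InterferenceConfig
from endocycle.mutation import MutationRates
from endocycle.population import (
    Grid,
    Holobiont,
    NutrientField,
    Population,
    divide_holobiont,
    nutrient_share,
    population_summary,
)
from endocycle.regulation import Origin


def _make_pop(w=10, h=10, influx=90.0, delta=0.0, seed=0, rates=None, interference=None):
    return Population(
        Grid(w, h),
        NutrientField.uniform(influx, height=h),
        rates=rates if rates is not None else MutationRates.zero(),
        interference=interference if interference is not None else InterferenceConfig.all_off(),
        delta=delta,
        seed=seed,
    )


class TestNutrientField:
    def test_default_has_eleven_distinct_sectors(self):
        f = NutrientField()
        assert f.sectors == 11
        assert len(set(f.sector_values)) == 11
        assert f.sector_values[0] == 10.0 and f.sector_values[-1] == 110.0

    def test_influx_constant_within_sector(self):
        f = NutrientField()
        rows_per = f.height // f.sectors
        for sec in range(f.sectors):
            vals = {f.influx((0, y)) for y in range(sec * rows_per, (sec + 1) * rows_per)}
            assert len(vals) == 1

    def test_geometry_must_divide(self):
        with pytest.raises(ValueError, match="not divisible"):
            NutrientField(height=100, sectors=11)


class TestNutrientShare:
    def test_lone_holobiont_share(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        pop = _make_pop(influx=90.0)
        pop.add_holobiont(hg, [sg, sg], (5, 5))
        A, k = nutrient_share(pop.grid, pop.field, (5, 5))
        assert A == pytest.approx(30.0)  # 90 / 3 cells
        assert k == 6  # floor(30/5)

    def test_doubling_cells_halves_share(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        pop = _make_pop(influx=90.0)
        pop.add_holobiont(hg, [sg, sg], (5, 5))
        A1, _ = nutrient_share(pop.grid, pop.field, (5, 5))
        pop.add_holobiont(hg, [sg, sg], (5, 6))  # 3 more cells in range
        A2, _ = nutrient_share(pop.grid, pop.field, (5, 5))
        assert A2 == pytest.approx(A1 / 2)

    def test_k_floor_is_one(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        pop = _make_pop(influx=10.0)
        pop.add_holobiont(hg, [sg] * 9, (5, 5))  # A = 1 -> k = 1
        _, k = nutrient_share(pop.grid, pop.field, (5, 5))
        assert k == 1

    def test_unoccupied_site_rejected(self, bootstrap_pair):
        pop = _make_pop()
        with pytest.raises(ValueError, match="not occupied"):
            nutrient_share(pop.grid, pop.field, (0, 0))


class TestGridGeometry:
    def test_toroidal_width_bounded_height(self):
        g = Grid(10, 10)
        n = g.neighborhood((0, 0))
        assert len(n) == 6  # top edge clips, width wraps
        assert (9, 0) in n and (9, 1) in n
        assert len(g.neighborhood((5, 5))) == 9

    def test_single_occupancy_enforced(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        pop = _make_pop()
        pop.add_holobiont(hg, [sg], (1, 1))
        with pytest.raises(ValueError, match="occupied"):
            pop.add_holobiont(hg, [sg], (1, 1))


class TestDivideHolobiont:
    def _ready_holobiont(self, genome, n_sym):
        host = Cell(genome=genome, origin=Origin.HOST, fork=genome.L,
                    passed=(Stage.G1, Stage.S, Stage.G2, Stage.M),
                    stage=Stage.M, divided_ready=True)
        syms = [Cell(genome=genome, origin=Origin.SYMBIONT) for _ in range(n_sym)]
        return Holobiont(host=host, symbionts=syms, site=(0, 0))

    def test_requires_ready_host(self, bootstrap_genome, rng):
        h = self._ready_holobiont(bootstrap_genome, 2)
        h.host.divided_ready = False
        with pytest.raises(ValueError, match="divided-ready"):
            divide_holobiont(h, rng)

    def test_single_symbiont_kills_one_daughter(self, bootstrap_genome, rng):
        lost = 0
        for _ in range(200):
            h = self._ready_holobiont(bootstrap_genome, 1)
            da, db, _ = divide_holobiont(h, rng)
            assert (len(da.symbionts) == 0) != (len(db.symbionts) == 0)
            lost += 1
        assert lost == 200

    def test_partition_is_binomial_half(self, bootstrap_genome):
        """Daughter counts over many divisions of a 4-symbiont holobiont
        follow Binomial(4, 1/2); both daughters survive with frequency
        7/8."""
        rng = np.random.default_rng(8)
        n = 20_000
        counts = np.zeros(5, dtype=int)
        both = 0
        for _ in range(n):
            h = self._ready_holobiont(bootstrap_genome, 4)
            da, db, _ = divide_holobiont(h, rng)
            assert len(da.symbionts) + len(db.symbionts) == 4
            counts[len(da.symbionts)] += 1
            both += bool(da.symbionts and db.symbionts)
        expected = np.array([sps.binom.pmf(i, 4, 0.5) for i in range(5)]) * n
        assert sps.chisquare(counts, expected).pvalue > 0.01
        se = np.sqrt((7 / 8) * (1 / 8) / n)
        assert abs(both / n - 7 / 8) < 3 * se


class TestStepPopulation:
    def test_empty_grid_stays_empty(self):
        pop = _make_pop()
        pop.step()
        assert not pop.grid.occupancy and pop.t == 1

    def test_occupancy_invariants_over_run(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        pop = _make_pop(delta=0.002, seed=5)
        pop.add_holobiont(hg, [sg, sg], (5, 5))
        for _ in range(400):
            pop.step()
            for site, h in pop.grid.occupancy.items():
                assert h.site == site
                assert len(h.symbionts) >= 1
                assert h.host.alive

    def test_full_grid_blocks_births(self, bootstrap_pair):
        """Births require an empty Moore neighbor: occupancy never
        exceeds capacity, and steps without a prior death produce no
        birth (divided-ready hosts stall instead)."""
        hg, sg = bootstrap_pair
        pop = _make_pop(w=3, h=3)
        for x in range(3):
            for y in range(3):
                pop.add_holobiont(hg, [sg, sg], (x, y))
        deaths_seen = 0
        for _ in range(200):
            pop.step()
            assert len(pop.grid.occupancy) <= 9
            step_events = [e for e in pop.events if e.step == pop.t]
            births = [e for e in step_events if e.kind == "birth"]
            if deaths_seen == 0:
                assert not births
            deaths_seen += sum(e.kind == "death" for e in step_events)

    def test_nonviable_population_goes_extinct_under_death(self):
        """Constitutively-M genomes die of the premature-M rule."""
        g = constitutive_m_genome()
        pop = _make_pop(delta=0.0, seed=1)
        for site in [(2, 2), (6, 6), (4, 7)]:
            pop.add_holobiont(g, [g, g], site)
        for _ in range(50):
            pop.step()
            if not pop.grid.occupancy:
                break
        assert not pop.grid.occupancy

    def test_determinism_same_seed_same_events(self, bootstrap_pair):
        hg, sg = bootstrap_pair

        def run():
            pop = _make_pop(delta=0.002, seed=42,
                            rates=MutationRates(), interference=InterferenceConfig())
            pop.add_holobiont(hg, [sg, sg], (3, 3))
            pop.add_holobiont(hg, [sg, sg], (7, 7))
            for _ in range(300):
                pop.step()
            return pop.events

        assert run() == run()

    def test_viable_clone_grows_toward_stable_density(self, bootstrap_pair):
        """With no deaths, mutation or interference, occupied fraction is
        monotone non-decreasing until saturation."""
        hg, sg = bootstrap_pair
        pop = _make_pop(w=20, h=20, influx=90.0, delta=0.0, seed=9)
        pop.add_holobiont(hg, [sg, sg], (10, 10))
        series = []
        for _ in range(1200):
            pop.step()
            series.append(len(pop.grid.occupancy))
        # growth to a plateau; individual premature-M deaths allow small
        # dips but never large drawdowns
        peak = np.maximum.accumulate(series)
        assert series[-1] >= 10
        assert all(s >= p - max(3, 0.3 * p) for s, p in zip(series, peak))


class TestSummary:
    def test_empty(self):
        pop = _make_pop()
        s = pop.summary()
        assert s["N"] == 0.0 and s["S_over_H"] is None

    def test_single_holobiont_fraction(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        pop = _make_pop(w=5, h=2)
        pop.add_holobiont(hg, [sg, sg], (0, 0))
        s = pop.summary()
        assert s["N"] == pytest.approx(0.1)
        assert s["S_over_H"] == 2.0
        assert s["mean_symbionts"] == 2.0
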