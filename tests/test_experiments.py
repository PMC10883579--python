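"""Assay harness: clonal growth, knockouts, competition, ancestry."""

import numpy as np
import pytest

import dendropy

from endocycle.experiments import (
    KNOCKOUT_TOGGLES,
    clonal_growth_assay,
    competition,
    knockout_panel,
    lineage_to_newick,
    mrca_of,
    reconstruct_ancestry,
)
from endocycle.fixtures import host_control_pair, nonviable_genome
from endocycle.interference import InterferenceConfig
from endocycle.mutation import MutationRates
from endocycle.population import Grid, NutrientField, Population


class TestClonalGrowth:
    def test_nonviable_reports_zero_without_error(self, rng):
        g = nonviable_genome()
        res = clonal_growth_assay(g, g, 90, toggles=InterferenceConfig.all_off(),
                                  T=600, seed=0, grid_size=(10, 10), delta=0.01)
        assert res.N_equilibrium == 0.0

    def test_bootstrap_persists(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        res = clonal_growth_assay(hg, sg, 90, toggles=InterferenceConfig.all_off(),
                                  T=1200, seed=0, grid_size=(12, 12))
        assert res.N_equilibrium > 0.0

    def test_same_seed_same_result(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        kw = dict(toggles=InterferenceConfig.all_off(), T=400, seed=3,
                  grid_size=(8, 8))
        a = clonal_growth_assay(hg, sg, 90, **kw)
        b = clonal_growth_assay(hg, sg, 90, **kw)
        assert a.N_equilibrium == b.N_equilibrium
        assert a.trajectory == b.trajectory

    def test_window_cannot_exceed_T(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        with pytest.raises(ValueError, match="window"):
            clonal_growth_assay(hg, sg, 90, T=100, window=200)


class TestKnockouts:
    def test_host_control_toy_needs_h_to_s_targeting(self):
        """A clone whose symbiont S-pattern depends on a dual-localized
        host product collapses when host-to-symbiont targeting is cut."""
        hg, sg = host_control_pair()
        base_cfg = InterferenceConfig(
            leakage_rate=0.0, leakage_host_to_symbiont=False,
            leakage_symbiont_to_host=False,
        )
        kw = dict(T=1200, seed=0, grid_size=(12, 12))
        on = clonal_growth_assay(hg, sg, 90, toggles=base_cfg, **kw)
        off = clonal_growth_assay(
            hg, sg, 90,
            toggles=base_cfg.with_knockout(targeting_host_to_symbiont=False), **kw,
        )
        assert on.N_equilibrium > 0.05
        assert off.N_equilibrium - on.N_equilibrium < -0.05

    def test_panel_reports_all_toggles_with_se(self, bootstrap_pair):
        """The panel covers both directions of both channels and returns
        a delta and standard error per knockout."""
        hg, sg = bootstrap_pair
        res = knockout_panel(hg, sg, 90, T=300, seeds=(0, 1),
                             grid_size=(8, 8), fill=0.15)
        expected = set(KNOCKOUT_TOGGLES) - {"baseline"}
        assert set(res.delta_N) == expected == set(res.se)
        assert len(expected) == 6
        assert 0.0 <= res.baseline_N <= 1.0
        assert all(np.isfinite(v) for v in res.delta_N.values())

    def test_noop_toggle_changes_nothing(self, bootstrap_pair):
        """For a clone with no cross-compartment products, targeting
        knockouts are no-ops: delta_N is exactly zero (same rng path)."""
        hg, sg = bootstrap_pair
        base_cfg = InterferenceConfig(
            leakage_rate=0.0, leakage_host_to_symbiont=False,
            leakage_symbiont_to_host=False,
        )
        kw = dict(T=500, seed=1, grid_size=(10, 10))
        a = clonal_growth_assay(hg, sg, 90, toggles=base_cfg, **kw)
        b = clonal_growth_assay(
            hg, sg, 90, toggles=base_cfg.with_knockout(
                targeting_host_to_symbiont=False, targeting_symbiont_to_host=False
            ), **kw,
        )
        assert b.N_equilibrium == a.N_equilibrium


class TestCompetition:
    def test_requires_nonempty(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        with pytest.raises(ValueError, match="nonempty"):
            competition([], [(hg, [sg])], T=10)

    def test_viable_beats_nonviable(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        nv = nonviable_genome()
        res = competition(
            [(hg, [sg, sg])], [(nv, [nv, nv])],
            T=3000, seed=0, grid=Grid(12, 8),
            fieldspec=NutrientField.uniform(90.0, height=8), delta=0.01,
        )
        assert res.winner == "A"
        assert res.final_density["B"] == 0.0

    def test_stop_at_fixation(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        nv = nonviable_genome()
        res = competition(
            [(hg, [sg, sg])], [(nv, [nv, nv])],
            T=5000, seed=0, grid=Grid(12, 8),
            fieldspec=NutrientField.uniform(90.0, height=8), delta=0.01,
        )
        assert res.stopped_at < 5000
        assert res.densities[-1][1] == 0.0

    def test_self_competition_is_symmetric(self, bootstrap_pair):
        """A vs A: each side wins about half the time."""
        hg, sg = bootstrap_pair
        wins = {"A": 0, "B": 0, None: 0}
        n = 12
        for seed in range(n):
            res = competition(
                [(hg, [sg, sg])], [(hg, [sg, sg])],
                T=4000, seed=seed, grid=Grid(8, 6),
                fieldspec=NutrientField.uniform(90.0, height=6),
                delta=0.01, fill=0.3,
            )
            wins[res.winner] += 1
        decided = wins["A"] + wins["B"]
        if decided:
            # 3-SE binomial band around 1/2
            se = np.sqrt(0.25 / decided)
            assert abs(wins["A"] / decided - 0.5) <= 3 * se + 1 / decided


def _brute_force_mrca(leaves, parents):
    paths = []
    for leaf in leaves:
        path = [leaf]
        while path[-1] in parents:
            path.append(parents[path[-1]])
        paths.append(set(path))
    common = set.intersection(*paths) if paths else set()
    if not common:
        return None
    # deepest common node = the one whose root path contains all others
    depth = {}
    for node in common:
        d, cur = 0, node
        while cur in parents:
            cur = parents[cur]
            d += 1
        depth[node] = d
    return max(common, key=lambda n: depth[n])


class TestAncestry:
    def test_siblings_have_parent_as_mrca(self):
        parents = {2: 1, 3: 1}
        assert mrca_of([2, 3], parents) == 1

    def test_single_lineage(self):
        parents = {2: 1, 3: 2}
        assert mrca_of([3], parents) == 3

    def test_disjoint_roots_have_no_mrca(self):
        assert mrca_of([1, 2], {}) is None

    def test_matches_brute_force_on_random_forests(self):
        """MRCA equals exhaustive root-path intersection on 100 random
        birth forests."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            n_roots = int(rng.integers(1, 3))
            parents = {}
            nodes = list(range(1, n_roots + 1))
            nxt = n_roots + 1
            while nxt <= n:
                parents[nxt] = int(nodes[rng.integers(0, len(nodes))])
                nodes.append(nxt)
                nxt += 1
            k = int(rng.integers(1, min(8, n)))
            leaves = [int(nodes[i]) for i in rng.choice(len(nodes), size=k, replace=False)]
            assert mrca_of(leaves, parents) == _brute_force_mrca(leaves, parents)

    def test_reconstruct_from_run(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        pop = Population(Grid(10, 10), NutrientField.uniform(90.0, height=10),
                         rates=MutationRates.zero(),
                         interference=InterferenceConfig.all_off(), delta=0.0, seed=2)
        pop.add_holobiont(hg, [sg, sg], (5, 5))
        for _ in range(800):
            pop.step()
        assert pop.grid.occupancy
        res = reconstruct_ancestry(pop)
        assert res["holobiont"].mrca is not None
        # everything descends from the single inoculant: its id roots the path
        assert res["holobiont"].path_to_root[0] == 1
        assert res["holobiont"].genomes[0] == hg

    def test_newick_export_parses(self, bootstrap_pair):
        hg, sg = bootstrap_pair
        pop = Population(Grid(8, 8), NutrientField.uniform(90.0, height=8),
                         rates=MutationRates.zero(),
                         interference=InterferenceConfig.all_off(), delta=0.0, seed=4)
        pop.add_holobiont(hg, [sg, sg], (4, 4))
        for _ in range(500):
            pop.step()
        text = lineage_to_newick(pop)
        trees = dendropy.TreeList.get(data=text, schema="newick")
        assert len(trees) >= 1
        labels = {leaf.taxon.label for t in trees for leaf in t.leaf_node_iter()}
        alive = {f"h{h.hid}" for h in pop.grid.holobionts()}
        assert alive <= labels
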