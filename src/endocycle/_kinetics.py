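"""Precompiled binding kinetics for the common cell-step path.

Genomes are immutable, so per-genome quantities -- site positions,
regulatory regions, the gene-product x binding-site affinity matrix --
are compiled once and cached. The fast step path applies only when a
cell carries no foreign products and none routed away; foreign influx
falls back to the general object-level route in
:mod:`endocycle.regulation`, which this module must agree with exactly
(checked distributionally by tests). The per-site categorical sampling
runs in a numba kernel when numba is importable, with an identical
pure-Python fallback.
"""

from __future__ import annotations

import numpy as np

from .genome import BindingSite, Genome, RegulatoryGene

__all__ = ["GenomeKinetics", "compile_kinetics"]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _kernel(aff, expr_idx, copies, region_starts, region_sites, weights, thresholds, u):
    n_sites = aff.shape[1]
    n_genes = len(thresholds)
    n_expr = len(expr_idx)
    bound = np.full(n_sites, -1, np.int64)
    for j in range(n_sites):
        z = 1.0
        for t in range(n_expr):
            z += aff[expr_idx[t], j] * copies[t]
        uu = u[j] * z - 1.0
        if uu > 0.0:
            for t in range(n_expr):
                uu -= aff[expr_idx[t], j] * copies[t]
                if uu <= 0.0:
                    bound[j] = expr_idx[t]
                    break
            else:  # float round-off guard
                bound[j] = expr_idx[n_expr - 1]
    expr_out = np.zeros(n_genes, np.bool_)
    for i in range(n_genes):
        tot = 0
        for r in range(region_starts[i], region_starts[i + 1]):
            b = bound[region_sites[r]]
            if b >= 0:
                tot += weights[b]
        expr_out[i] = tot >= thresholds[i]
    return expr_out


def _kernel_py(aff, expr_idx, copies, region_starts, region_sites, weights, thresholds, u):
    n_sites = aff.shape[1]
    n_genes = len(thresholds)
    n_expr = len(expr_idx)
    bound = [-1] * n_sites
    for j in range(n_sites):
        z = 1.0
        for t in range(n_expr):
            z += aff[expr_idx[t], j] * copies[t]
        uu = u[j] * z - 1.0
        if uu > 0.0:
            assigned = False
            for t in range(n_expr):
                uu -= aff[expr_idx[t], j] * copies[t]
                if uu <= 0.0:
                    bound[j] = expr_idx[t]
                    assigned = True
                    break
            if not assigned:
                bound[j] = expr_idx[n_expr - 1]
    out = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        tot = 0
        for r in range(region_starts[i], region_starts[i + 1]):
            b = bound[region_sites[r]]
            if b >= 0:
                tot += weights[b]
        out[i] = tot >= thresholds[i]
    return out


_sample = _kernel if _HAVE_NUMBA else _kernel_py


class GenomeKinetics:
    __slots__ = (
        "gene_positions",
        "site_positions",
        "aff",
        "region_starts",
        "region_sites",
        "weights",
        "thresholds",
        "type_ids",
        "core_index",
        "any_routing",
    )

    def __init__(self, genome: Genome, c: float, s: float):
        self.gene_positions: list[int] = genome.gene_positions()
        self.site_positions: list[int] = genome.site_positions()
        site_index = {pos: j for j, pos in enumerate(self.site_positions)}
        genes: list[RegulatoryGene] = [genome[gi] for gi in self.gene_positions]
        sites: list[BindingSite] = [genome[sp] for sp in self.site_positions]

        starts = [0]
        flat: list[int] = []
        for gi in self.gene_positions:
            for p in genome.regulatory_region(gi):
                flat.append(site_index[p])
            starts.append(len(flat))
        self.region_starts = np.asarray(starts, dtype=np.int64)
        self.region_sites = np.asarray(flat, dtype=np.int64)
        self.weights = np.asarray([g.weight for g in genes], dtype=np.int64)
        self.thresholds = np.asarray([g.threshold for g in genes], dtype=np.int64)
        self.type_ids = [g.type_id for g in genes]

        aff = np.empty((len(genes), len(sites)), dtype=np.float64)
        for i, g in enumerate(genes):
            for j, site in enumerate(sites):
                d = sum(x != y for x, y in zip(g.binding_seq, site.seq))
                aff[i, j] = c * (s ** d)
        self.aff = aff

        self.core_index: list[list[int]] = [[] for _ in range(5)]
        for i, t in enumerate(self.type_ids):
            if 1 <= t <= 5:
                self.core_index[t - 1].append(i)
        # genes whose peptide is not 00: routing may remove the product
        # from its own compartment, which disables the fast path
        self.any_routing = any(
            g.signal_peptide != (0, 0) for g in genes
        )

    def step_expression(
        self, expressed: list[int], copies: list[int], rng
    ) -> tuple[tuple[bool, ...], tuple[int, ...]]:
        """Sample occupancy for a purely native pool; return the next
        expression vector and its 5-bit core pattern."""
        n_sites = len(self.site_positions)
        if expressed and n_sites:
            u = rng.random(n_sites)
            expr_arr = _sample(
                self.aff,
                np.asarray(expressed, dtype=np.int64),
                np.asarray(copies, dtype=np.float64),
                self.region_starts,
                self.region_sites,
                self.weights,
                self.thresholds,
                u,
            )
            expr = tuple(expr_arr.tolist())
        else:
            expr = tuple(
                0 >= self.thresholds[i] for i in range(len(self.thresholds))
            )
        bits = tuple(
            1 if any(expr[i] for i in idx) else 0 for idx in self.core_index
        )
        return expr, bits


def compile_kinetics(genome: Genome, c: float, s: float) -> GenomeKinetics:
    """Kinetics are cached on the (immutable) genome instance itself, so
    repeated lookups cost one dict probe rather than a deep equality
    check."""
    cache = genome._kin
    if cache is None:
        cache = genome._kin = {}
    kin = cache.get((c, s))
    if kin is None:
        kin = cache[(c, s)] = GenomeKinetics(genome, c, s)
    return kin
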