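# Methods

`endocycle` simulates the evolution of an obligate endosymbiosis between
two simple cells: a host and one or more intracellular symbionts that
together form a *holobiont*. The model couples four organizational
levels — genome, gene-regulatory network, cell cycle, and spatial
ecology — and adds three molecular-interference channels between host
and symbiont. This note describes the model as implemented, the
parameters that matter, and the choices made where the design was open.

## Genomes and regulation

Each cell carries a beads-on-a-string genome: an ordered list of
regulatory genes, binding sites and passive household genes. Genome size
`L` is the bead count; the regulatory repertoire `R` counts genes plus
sites. A gene holds a binding sequence (a B-bit vector, B = 20 by
default), a 2-bit signal peptide, an integer regulatory weight
(clamped to [-3, 3]) and an activation threshold (clamped to [-2, 5]).

Expression is Boolean and synchronous. Each timestep, the products of
currently expressed genes compete for every binding site independently.
A product's unnormalized binding mass for a site is

    a = c · s^d · copies,   d = Hamming(product, site),

with c = 10 and s = 0.5 by default; the site draws one occupant from the
categorical distribution that also gives the empty outcome mass 1. Two
consequences are deliberate: even a perfect match binds with probability
a/(1+a) < 1, and a replicated gene (2 copies) roughly doubles a
low-affinity binding probability — the dosage signal on which
replication checkpoints can be built. A gene turns on when the summed
weights of occupants in its *regulatory region* — the contiguous run of
binding sites immediately upstream, broken by any gene or household
bead — reach its threshold. Repression exists only through negative
weights; weights live on products (genes), not on sites.

## Cell cycle

The joint Boolean state of the five core gene types g1–g5 is matched
against a table of four 5-bit patterns defining the stages G1, S, G2
and M (defaults G1=10001, S=11001, G2=11101, M=11011, chosen together
with the bootstrap circuit below; the table is configurable). The stage
machine is checkpoint-like: a decoded pattern advances the stage only if
it is the exact successor of the last stage passed this cycle; any other
pattern stalls the stage while expression keeps evolving. Decoding M
prematurely — without G1, S, G2 passed in order, or with the replication
fork short of the genome end — kills the cell. A legitimate M makes the
cell divided-ready; daughters inherit the parent's expression state,
reset fork and stage history, and mutate independently.

Replication happens only in S: the fork advances `k` beads per step,
where `k` comes from local nutrients (below). The fastest possible cycle
for genome size L is `tau_min = ceil(L/k) + 3` (one step each for G1,
G2, M); the efficiency of an observed cycle is `e = tau_min / tau`. The
`tau_min` formula is this package's convention — the floor implied by
the one-step-per-stage progression rule — so `e` values are comparable
only within this artifact.

Foreign products (leaked or targeted, below) act like native products in
every respect: they bind sites, contribute weights, and set a core
pattern bit if — and only if — they are bit-identical to a native gene of
the same core type. Divergence of core-gene sequences therefore shields
a cell from having its stage dictated by its partner.

## Interference channels

* **Leakage.** Every expressed gene's product crosses compartments with
  probability l = 0.01 per gene per symbiont per timestep, in both
  directions (each direction can be disabled). Deliveries carry one
  copy; foreign products never re-leak.
* **Targeting.** The 2-bit signal peptide routes products: 10 host only,
  01 every symbiont, 00 the encoding compartment, 11 both. A one-hot
  peptide pointing away from the encoding compartment removes the
  product from its own cell. Knockouts drop cross-compartment deliveries
  of one direction while native-compartment presence is untouched.
* **Gene transfer.** A newly divided host (symbiont) draws each
  regulatory-gene bead of each symbiont (of the host) with probability
  mu_t = 2.0e-5; half the transfers copy the bead, half cut it from the
  donor; the bare gene inserts at a uniform position (no flanking
  sites, so a transferred gene must acquire regulation by subsequent
  mutation).

## Mutation

Applied independently to each daughter at division, in a fixed order:
per-bead structural events (duplication inserts the copy adjacent
downstream; deletion; relocation to a uniform position — precedence
del > rel > dup when one bead draws several), per-genome innovations (a
random new site, or a new gene with a fresh non-core type id, silent
peptide 00, uniform weight and threshold), then per-element value
mutations (sequence bit flips at mu_B = 3.3e-5/bit, peptide flips at
mu_S = 1.0e-5/bit, ±1 weight and threshold steps at 1.67e-4/gene,
clamped). Structural rates are 1.67e-4 per bead; innovation rates
1.67e-3 (sites) and 1.67e-4 (genes) per genome. Internally the Bernoulli
draws are realized as a binomial count plus a uniform position sample —
distributionally identical and much faster at small rates.

## Ecology

Holobionts occupy single sites of a grid (default 45 × 110, toroidal in
width, bounded in height). Nutrient influx is constant in time and
arranged in 11 horizontal sectors linearly spaced from 10 to 110. All
cells in a site's 3×3 Moore neighborhood share the influx equally:
`A = influx / cells`, and the replication budget is
`k = max(1, floor(A / rho))` with rho = 5 beads per nutrient unit. More
symbionts or neighbors mean slower replication — the feedback that
prices symbiont number.

Each synchronous timestep: budgets are computed from current occupancy;
targeting then leakage fill foreign pools; every cell steps (randomized
site order); a dividing symbiont is replaced in place by its two
daughters; a dividing host splits the holobiont into a random empty
Moore neighbor (no empty neighbor: the host stalls divided-ready and
retries), partitioning symbionts binomially — a daughter drawing zero
symbionts is dead on arrival; deaths are applied (premature-M, symbiont
loss, and a basal holobiont death probability delta = 0.002 per step,
configurable and possibly 0, which frees space for competition); all
events append to the lineage log. A single master seed expands into
named substreams (ecology, mutation, binding, assay) so runs are
bit-reproducible; snapshots carry full rng states and restore to exact
continuations.

## The bootstrap holobiont

Host and symbiont start bit-identical: L = 64 with 50 household beads
and a 14-bead regulatory repertoire (five core genes, nine sites) wired
as a primitive but viable cycle. The circuit uses the dosage clock
directly: g1 sits at the replication terminus (its product has 2 copies
exactly when replication is complete) and g5 at the origin; both are
constitutive. g2, driven by g5's product through one medium-affinity
site, flickers and carries G1 → S. g3 is the S-exit trigger: six
low-affinity sites all reading g1's product with threshold 6 — an AND
gate whose firing probability is ~7.7e-4 per step before replication
completes and ~1e-2 after, a *stochastic* replication checkpoint. g4
drives M and needs the products of both g3 and g2 from the previous
step. All bootstrap peptides are 00 (products stay where they are
encoded), so the initial holobiont has no cross-compartment regulation
and interference channels start as pure disturbance.

Consequences worth knowing: the expected cycle at high nutrients
(k = 18) is ~130–170 steps, dominated by the post-replication wait of
the AND gate, so the bootstrap's efficiency e is low (~0.05) —
consistent with a primitive ancestor that evolution is expected to
improve. The gate's false-fire path kills roughly 0.3–2% of cycles
(more at low k, which largely confines the initial population to rich
sectors), so single-cell viability runs pass for most but not all
seeds, and population runs show continuous background turnover even at
delta = 0.

## Assays

Clonal growth assays seed a uniform-influx grid with one holobiont
genotype (two symbionts each, 10% fill), force mutation rates to zero so
the measured density reflects the genotype, run T steps (default 5000)
and report the mean occupied fraction N over the last 20% of T; an
extinct clone reports N = 0. Knockout panels repeat the assay with each
leakage/targeting direction disabled and report delta_N with a
Monte-Carlo standard error over seeds. Competition seeds the two grid
halves from two saved populations at equal density, runs without
mutation, and stops at fixation or the step budget. Ancestry
reconstruction computes the most recent common ancestor of the living
population from the birth-event forest (holobiont/host lineages) and
from the per-cell parent map (symbiont lineages); lineages export to
Newick with branch lengths in timesteps.

The hand-wired assay fixtures (`endocycle.fixtures`) are engineered,
synthetic constructions: a household-only genome (stalls forever), a
constitutive-M genome (dies by the premature-M rule), a *host-control*
pair whose symbiont cycle requires a dual-localized host product, and a
*symbiont-control* pair whose host M-stage requires a host-localized
symbiont product. The control pairs are built so the gated sum cannot be
completed by stray cross-bindings (weight/threshold margins of 2).

## What the generator does and does not emulate

The synthetic bootstrap and toys exercise every mechanism the simulator
implements — stochastic binding, dosage sensing, staged death,
interference, spatial competition — under the model's published
constants. They do not reproduce any *evolved* genotype: multi-month,
1e7-step evolutionary outcomes (which coordination mechanism fixes,
genome-size trajectories, the printed densities of evolved ancestors)
are population-scale contingent results outside desk scale, and nothing
in the test suite should be read as evidence about them.

## Numerical choices and limitations

Affinities are exact IEEE doubles of c·s^d; the compiled (numba) sampling
kernel and the object-level sampler implement the same categorical draw
and are checked against each other distributionally. Ties in the
categorical inverse-CDF are broken toward the earlier product (a
measure-zero event). Degenerate inputs: an empty genome never expresses
and never dies; k is floored at 1 so replication always progresses in S;
a genome shortened below the fork clamps the fork. Update order over
sites is randomized per step to avoid spatial artifacts; placement
conflicts resolve by processing order. Known limitations: products live
one timestep (no decay dynamics); nutrient sharing is instantaneous
(no depletion state or diffusion); expression alignment across
structural mutations is positional, so a rearranged daughter may start
with an approximate expression state for one step.

## Problem sizes used in the shipped checks

Leakage recovery uses 1e6 gene-symbiont-steps; mutation recovery 1e6
divisions of the 64-bead genome; the binding-sampler comparison 1e5
draws per pool; partition statistics 1e5 holobiont divisions; the
whole-model run 1e4 timesteps on the 45×110 gradient from a 100-
holobiont inoculum. These sizes give 3-standard-error resolution on the
recovered constants while keeping the default suite inside a desktop
time budget.
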