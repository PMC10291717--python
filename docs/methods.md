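# Methods

This note documents the models implemented in `multimut`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Network construction

A community state is two bipartite interaction tables — pollination
(plant × pollinator) and seed dispersal (plant × frugivore) — with
non-negative integer counts. Zero-count rows are observation placeholders
and are dropped at read time; a species with no links in a layer is simply
absent from that layer. Plants and animals occupy disjoint, case-sensitive
id namespaces; a species appearing in both is rejected.

Intralayer weights divide each count by the layer total, so each layer's
weights sum to 1 (asserted to 1e-12 in the tests). Interlayer coupling is
carried by plants active in both layers: plant *j* with *p* pollinator and
*d* disperser partners mediates `n_j = p × d` indirect links — *distinct
species pairs*, not weighted walks; the downstream connectivity analysis is
explicitly binary ("at least one shared plant"), which is why pair-level
accounting is used. The interlayer weight `n_j / L_tot` is an undirected
self-link between the plant's two state nodes. If no plant spans both
layers the network is valid but flagged `layer_disconnected`.

Serialization keeps integer counts; weights are re-derived on read with the
same arithmetic, so round-trips are bit-exact.

## Modularity

Module detection minimizes the two-level map equation on the flattened
state-node graph (intralayer links plus explicit interlayer self-links; no
relax-rate coupling — the interlayer weights already put both link types on
the same [0, 1] scale). The optimizer is igraph's Infomap implementation,
run `trials` times (default 100 for final analyses, 20 in the pipeline
defaults) keeping the best partition; it is deterministic given the seed.
The test suite carries an independent two-level map-equation evaluator and
verifies, by exhaustive partition enumeration on small graphs, that the
detected partition attains the global codelength minimum. Module ids are
relabelled 1..K by decreasing size, ties broken by first appearance.

The null model shuffles each layer's count matrix with the Patefield
fixed-marginals algorithm (`scipy.stats.random_table`), preserving every
species' total interaction count exactly, then rebuilds all weights —
including the interlayer weights, which respond to the shuffle through the
changed partner sets. Degenerate single-row/column matrices are fully
determined by their marginals and are passed through unchanged (the scipy
sampler misbehaves on them). Shuffled networks that lose all interlayer
plants are retained; their module count is computed on the two uncoupled
layers. The two-tailed empirical p-value uses the add-one correction
`p = min(1, 2·min(r_ge+1, r_le+1)/(n+1))`; a z-score against the shuffled
distribution is reported alongside for users who prefer a parametric
summary. The number of shuffles defaults to 1000 and is configurable.

## Structural roles

Within-module degree `z` standardizes the count of links into a node's own
module over that module's members (population SD; an all-equal module gets
z = 0 throughout). Among-module connectivity is the participation
coefficient `c = 1 − Σ_m (k_m/k)²`; isolated nodes get c = 0 by
convention. Degrees are binary (link presence) on the same flattened graph
used for detection, so the interlayer self-link counts as one link between
a plant's two state nodes; a weighted variant is available as a diagnostic
(`assign_roles(..., weighted=True)`). The four roles partition the (z, c)
plane at z = 2.5 and c = 0.62 with boundaries inclusive on ≤.

A plant active in both layers receives two independent role assignments,
one per state node (they are not pooled even when the two state nodes share
a module — independent scoring keeps the role interpretable per layer).
Role percentages are therefore reported both over state nodes and over
physical species (each species resolved to its most connected role); the
two denominators differ only by the doubly-scored plants. Role transitions
between two community states are tallied per (species, layer) state node,
restricted to state nodes present in both, in four groups: pollinators,
dispersers, plants-in-pollination, plants-in-dispersal.

## Coextinction model

Species `y` has intrinsic mutualism dependence `R_y ∈ [0, 1]` and partner
dependences `d_yx = w_yx / Σ_k w_yk` from the intralayer weights. Plants
normalize over **both** layers by default — one demographic budget per
plant population served by two mutualisms — which is exactly what lets
cascades cross from one interaction type to the other; a per-layer
normalization (each layer's sub-row normalized, then averaged with equal
mass) is available as a configuration switch for sensitivity analysis.

When a species is lost, every surviving partner undergoes one Bernoulli
trial per lost partner with success probability `R_y · d_yx`, at the round
the partner is lost; trials are independent and a species that survives all
of them persists even with zero remaining partners (facultative-mutualism
interpretation). Equilibrium is a round with no new extinction. The
Monte-Carlo mean of `E` (% extinct, primary included) is validated against
exact enumeration of the Bernoulli outcome tree on all ≤5-species fixtures
(agreement within 3 standard errors at 10⁵ replicates).

`R` values are supplied per species or per trophic group; when no empirical
(diet-based) values are available the default draws one `R ~ Uniform(0,1)`
per species from a fixed seed. Users with empirical dependence estimates
should pass them explicitly — the uniform default spans the facultative–
obligate range rather than representing any particular community.

**Sequential removal.** Removal order follows the scenario: most-to-least
connected role (network hub, module hub, connector, peripheral),
least-to-most, or uniformly random; the order within a role class is
redrawn at random in every run. Roles are computed once on the original
network; a plant with two state-node roles is ranked by the more connected
one, since cascades act on species. Species already extinct through
coextinction are skipped as primary targets. The robustness curve plots
proportion of species remaining against primary removals over the initial
species count; when cascades empty the network early the curve is closed
with a terminal (1, 0) point, which adds zero area. This convention makes
the no-propagation case exact: with all R = 0 the curve is y = 1 − x and
the trapezoidal AUC is 0.5 under every scenario — a closed form the tests
assert exactly. AUC is reported as mean ± SD over 1000 runs by default.

**Size control.** Because species richness correlates with most structural
properties, the larger network can be bootstrapped down to the smaller
one's per-group species counts: each replicate samples species without
replacement, induces the sub-network on the raw counts, rebuilds weights
and dependences, and reruns the experiments. Replicates report the grand
mean single-removal `E` and the random-order AUC; role-ordered scenarios
are not rerun per replicate, as each would require a full modularity and
role recomputation on the resampled network, and the random-order AUC
carries the size signal.

**Seeding.** Every experiment spawns per-replicate RNG substreams
(`numpy.random.SeedSequence`) from one root seed, so results are
reproducible and independent of iteration order.

## Synthetic data generator

The generator targets the statistical signature of temperate-forest
mutualistic visitation data, not any particular site: log-normal species
activities (σ = 1 on the log scale) give the heavy-tailed, few-generalists
degree structure typical of visitation records; counts are Poisson draws
around activity products scaled to an expected layer total (1200 pollination
and 400 dispersal events in the intact-like preset — a few hundred to ~10³
events is a realistic field-season total, and the ratio reflects dispersal
layers being much more thinly sampled); every configured species is forced
to realize at least one interaction per layer of membership. The shipped
presets mirror the magnitudes of a paired invasion study: `intact_like`
(37 plants, 95 pollinators, 4 dispersers, 22% interlayer plants) and
`invaded_like` (24/67/4, 21%, lower event totals). The dispersal layer
contains the designated interlayer plants plus two dispersal-only plants;
dispersers are few and broadly connected, reproducing the strong
pollinator/disperser asymmetry in indirect-link counts. `generate_state_pair`
gives two states partially sharing species ids (80% overlap by default,
taken from the head of each pool so interlayer plants tend to be shared),
supporting turnover and role-transition analyses.

What the generator does **not** emulate: phenological structure (seasons
are pooled), sampling effort heterogeneity beyond Poisson noise,
interaction rewiring, trait- or phylogeny-driven link constraints, and any
mechanistic herbivory effect — the "invaded" state is emulated only through
its network-level signature (fewer species, fewer events, slightly lower
interlayer fraction). Tests passing on synthetic data therefore demonstrate
the correctness and calibration of the algorithms under realistic
magnitudes, not field-data conclusions. An optional planted block structure
(k blocks per layer, cross-block rates damped ×0.02) creates well-separated
modules for recovery calibration: detection recovers ≥ k modules in > 90%
of seeds at the tested sizes.

## Numerical choices and degenerate inputs

- Weight sums asserted to 1e-12; all probability comparisons use strict
  `rng.random() < p`.
- Empty layers raise; a layer pair with no shared plants yields a valid,
  flagged network.
- `sd = 0` modules give z = 0; isolated nodes give c = 0.
- Module-count p-values are floored at `2/(n+1)` and capped at 1.
- The robustness x-axis uses primary removals; coextinctions only lower y.
- Single-row/column count matrices are their own (unique) shuffle.

## Known limitations

- No interaction rewiring after extinctions; no abundance dynamics. `E` and
  AUC therefore bound, rather than predict, demographic outcomes.
- Inferential statistics (GLMMs on connectivity or E/AUC, post hoc
  contrasts) are deliberately out of scope; the modules export tidy
  per-species tables for any statistics package.
- The map-equation optimizer is stochastic; module counts on weakly
  structured networks can vary by ±1–2 across seeds. The null test absorbs
  this by using the same detection settings for observed and shuffled
  networks.
- Bootstrap size control resamples species, not sampling effort; it
  controls for richness, not for observation intensity.
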