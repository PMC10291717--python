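# multimut

Multilayer analysis of coupled pollination and seed-dispersal networks:
construction, connectivity, modularity, species structural roles, and
stochastic coextinction simulations.

Ecological communities rarely run on a single interaction type. Flowering
plants need pollinators to reproduce *and* frugivores to disperse their
seeds, so a disturbance that hits one mutualism can cascade into the other
through the plants they share. `multimut` is a toolkit for ecologists who
want to quantify that coupling: it represents a community as a two-layer
multilayer network — a pollination layer α and a seed-dispersal layer β
sharing plant nodes — and asks how the network's structure shapes its
tolerance to species loss. It was designed for comparing community states
(e.g. sites invaded by non-native ungulates versus intact sites), but works
for any pair of plant–animal interaction layers linked by shared plants.

## The model

**Network construction.** From raw visit/feeding counts `f_ji`, intralayer
link weights are `w_jiα = f_ji / Vα` (layer totals `Vα`, so each layer's
weights sum to 1). An *indirect link* is a pollinator–disperser species
pair connected by a two-step walk through a shared plant; a plant `j` with
`p_j` pollinator partners and `d_j` disperser partners mediates
`n_j = p_j × d_j` of them. The interlayer link coupling plant `j`'s two
state nodes has weight `w_jαβ = n_j / L_tot`, with `L_tot = Σ_j n_j`. Both
link types live on [0, 1], so flow-based statistics are not biased toward
either.

**Modularity.** Modules of state nodes (species, layer) are found by
minimizing the map equation (Infomap) on the flattened multilayer graph
with its explicit interlayer links. The observed module count is tested
against a null ensemble in which each layer's count matrix is shuffled with
the Patefield algorithm (fixed row and column marginals — every species
keeps its total interaction count), and an empirical two-tailed p-value is
reported.

**Structural roles.** Each state node gets a within-module degree
`z` (standardized links to its own module) and an among-module connectivity
`c = 1 − Σ_m (k_m/k)²`, classifying it as peripheral (z ≤ 2.5, c ≤ 0.62),
connector (z ≤ 2.5, c > 0.62), module hub (z > 2.5, c ≤ 0.62) or network
hub (z > 2.5, c > 0.62). Plants active in both layers carry two roles.

**Stability.** A stochastic coextinction model: species `y` depends on each
partner `x` with `d_yx` (row-normalized weights; a plant's row spans both
layers) and carries an intrinsic mutualism dependence `R_y ∈ [0, 1]`. When
`x` goes extinct, `y` goes extinct with probability `R_y · d_yx`, one
Bernoulli trial per lost partner, iterated to equilibrium. Two experiments:
single-removal disturbance propagation `E` (% of species extinct,
averaged over 100 cascades per species) and sequential-removal robustness
(AUC of the proportion-remaining curve under role-ordered or random
removal, 1000 runs).

## Worked example

```python
from multimut import (
    assemble_multilayer, detect_modules, assign_roles, build_dependencies,
    indirect_link_matrix, per_species_indirect_stats,
    single_removal_experiment, robustness_experiment, load_preset, generate_community,
)
from multimut.connectivity import group_summary
from multimut.coextinction import random_R, species_role_map

pol, disp = generate_community(load_preset("intact_like", seed=1))
net = assemble_multilayer(pol, disp)
print(net.summary())

stats = per_species_indirect_stats(indirect_link_matrix(net))
print(group_summary(stats).round(2).to_string(index=False))

partition = detect_modules(net, seed=1, trials=50)
print(f"{partition.n_modules} modules")

roles = assign_roles(net, partition)
print(roles["role"].value_counts().to_string())

deps = build_dependencies(net, random_R(net, seed=1))
E = single_removal_experiment(deps, reps=100, seed=1)
print(f"mean E = {E['mean_E'].mean():.2f}%")
aucs = robustness_experiment(deps, "most-to-least", species_role_map(roles), n_runs=200, seed=1)
print(f"AUC (most-to-least) = {aucs['auc'].mean():.3f}")
```

prints

```
{'state': 'intact', 'n_plants': 37, 'n_pollinators': 95, 'n_dispersers': 4,
 'n_species': 136, 'n_interlayer_plants': 8,
 'interlayer_plants': ['P001', ..., 'P008'], 'l_tot': 567, 'layer_disconnected': False}
trophic_group  n_species  mean_count  sd_count  se_count  mean_proportion
    disperser          4       69.00      9.45      4.73             0.73
   pollinator         95        2.91      1.54      0.16             0.73
9 modules
role
peripheral    131
connector       9
module hub      4
mean E = 1.44%
AUC (most-to-least) = 0.275
```

Reading this: the synthetic intact-like community has 136 species, 8 of its
37 plants couple the two mutualisms (`l_tot` = 567 indirect links). Each of
the 4 dispersers reaches ~69 pollinators indirectly through shared plants,
while a typical pollinator reaches ~2.9 dispersers — the asymmetry expected
when few generalist frugivores serve many plants. The map equation finds 9
modules; most state nodes are peripheral. Removing one random species
extinguishes on average 1.4% of the community, and removing species from
the most to the least connected role collapses it with a robustness AUC of
0.275 (0.5 would mean no cascades at all).

The same analyses are available from the shell:

```bash
multimut simulate --seed 1 --out interactions.csv
multimut run-all --seed 1 --outdir out/       # full two-state pipeline
multimut compare out/summary.json
```

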