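"""Stochastic coextinction cascades on the three-trophic-group network.

The cascade model follows the stochastic coextinction framework for
mutualistic networks: each species ``y`` carries an intrinsic demographic
dependence on mutualism ``R_y ∈ [0, 1]`` and a dependence ``d_yx`` on each
partner ``x`` (its relative interaction strength, rows summing to 1).  When
``x`` goes extinct, every surviving partner ``y`` goes extinct with
probability ``R_y * d_yx`` — one Bernoulli trial per lost partner, at the
round the partner is lost.  Rounds repeat until no new extinction occurs.

Plants take part in both pollination and seed dispersal, so their
dependence rows span both layers by default (one demographic budget per
plant population); this is what lets a disturbance in one mutualism cascade
into the other.  A species that survives all trials persists even with no
remaining partners (facultative interpretation).

Two experiments quantify stability:

* *disturbance propagation*: remove one species, run to equilibrium, report
  E = percentage of species extinct (the primary removal included);
* *robustness*: remove species sequentially — ordered by structural role
  (most-to-least or least-to-most connected) or at random — and report the
  area under the curve of proportion of species remaining vs proportion of
  species removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DISPERSAL, POLLINATION, MultilayerNetwork
from .roles import ROLE_ORDER

SCENARIOS = ("most-to-least", "least-to-most", "random")


@dataclass
class DependencyStructure:
    """Per-species partner dependences ``d_ij`` and intrinsic dependences ``R_i``."""

    partners: dict[str, dict[str, float]]  # species -> {partner: d_ij}, rows sum to 1
    R: dict[str, float]
    groups: dict[str, str]  # species -> trophic group

    @property
    def species(self) -> list[str]:
        return sorted(self.partners)

    @property
    def n_species(self) -> int:
        return len(self.partners)


@dataclass
class CascadeResult:
    primary: str
    extinct: set[str]
    E: float  # percentage of species extinct at equilibrium, primary included


@dataclass
class RobustnessCurve:
    scenario: str
    x: np.ndarray  # proportion of species removed (primary removals / N)
    y: np.ndarray  # proportion of species remaining
    auc: float
    seed: int | None = field(default=None)


def build_dependencies(
    network: MultilayerNetwork,
    R_config: float | dict[str, float],
    plant_normalization: str = "both-layers",
) -> DependencyStructure:
    """Derive partner dependences from intralayer weights and attach R values.

    ``d_ij = w_ij / sum_k w_ik``.  Animals interact in a single layer; for
    plants the normalization spans both layers by default
    (``plant_normalization="both-layers"``) or each layer separately
    (``"per-layer"``, in which case a plant's row is normalized within each
    layer and then the two layers are averaged with equal mass).

    ``R_config`` is either one value for all species, or a mapping keyed by
    species id and/or trophic group name.
    """
    if plant_normalization not in ("both-layers", "per-layer"):
        raise ValueError(f"unknown plant_normalization {plant_normalization!r}")
    raw: dict[str, dict[str, float]] = {}
    by_layer: dict[str, dict[str, dict[str, float]]] = {}
    for layer in (POLLINATION, DISPERSAL):
        for plant, animal, weight in network.layers[layer][
            ["plant", "animal", "weight"]
        ].itertuples(index=False):
            w = float(weight)
            raw.setdefault(plant, {})[animal] = raw.get(plant, {}).get(animal, 0.0) + w
            raw.setdefault(animal, {})[plant] = raw.get(animal, {}).get(plant, 0.0) + w
            by_layer.setdefault(plant, {}).setdefault(layer, {})[animal] = (
                by_layer.get(plant, {}).get(layer, {}).get(animal, 0.0) + w
            )
    groups = {sp: network.trophic_group(sp) for sp in raw}
    partners: dict[str, dict[str, float]] = {}
    for sp, row in raw.items():
        if plant_normalization == "per-layer" and groups[sp] == "plant":
            layers = by_layer[sp]
            merged: dict[str, float] = {}
            for layer_row in layers.values():
                total = sum(layer_row.values())
                for partner, w in layer_row.items():
                    merged[partner] = merged.get(partner, 0.0) + w / total / len(layers)
            partners[sp] = merged
        else:
            total = sum(row.values())
            partners[sp] = {partner: w / total for partner, w in row.items()}
    R: dict[str, float] = {}
    for sp in partners:
        if isinstance(R_config, dict):
            value = R_config.get(sp, R_config.get(groups[sp]))
            if value is None:
                raise ValueError(f"no R value for species {sp!r} (group {groups[sp]})")
        else:
            value = R_config
        if not 0.0 <= float(value) <= 1.0:
            raise ValueError(f"R must lie in [0, 1]; got {value} for {sp!r}")
        R[sp] = float(value)
    return DependencyStructure(partners=partners, R=R, groups=groups)


def random_R(
    network: MultilayerNetwork, seed: int | np.random.Generator = 0
) -> dict[str, float]:
    """Draw one R ~ Uniform(0, 1) per species, reproducibly.

    Default when no diet-based empirical R values are supplied; species are
    processed in sorted order so the mapping depends only on the seed and
    the species pool.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    species = sorted(network.plants | network.pollinators | network.dispersers)
    draws = rng.random(len(species))
    return dict(zip(species, draws))


def simulate_cascade(
    deps: DependencyStructure, primary: str, rng: np.random.Generator
) -> CascadeResult:
    """One stochastic cascade from a single primary removal, to equilibrium."""
    if primary not in deps.partners:
        raise KeyError(f"species {primary!r} not in network")
    extinct = {primary}
    newly = [primary]
    while newly:
        next_new: list[str] = []
        doomed: set[str] = set()
        for x in newly:
            for y, _ in sorted(deps.partners[x].items()):
                if y in extinct or y in doomed:
                    continue
                if rng.random() < deps.R[y] * deps.partners[y][x]:
                    doomed.add(y)
                    next_new.append(y)
        extinct.update(doomed)
        newly = next_new
    return CascadeResult(primary=primary, extinct=extinct, E=100.0 * len(extinct) / deps.n_species)


def single_removal_experiment(
    deps: DependencyStructure,
    reps: int = 100,
    seed: int = 0,
    roles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Mean E per species over ``reps`` independent cascades.

    Each (species, rep) pair gets its own RNG substream spawned from the
    root seed, so results are reproducible and independent of iteration
    order.  If ``roles`` maps species to structural roles the output gains
    a ``role`` column for downstream grouping.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(deps.species))
    rows = []
    for sp, stream in zip(deps.species, streams):
        rng = np.random.default_rng(stream)
        values = np.fromiter(
            (simulate_cascade(deps, sp, rng).E for _ in range(reps)), dtype=float, count=reps
        )
        rows.append(
            {
                "species": sp,
                "trophic_group": deps.groups[sp],
                "mean_E": float(values.mean()),
                "sd_E": float(values.std(ddof=1)) if reps > 1 else 0.0,
                "reps": reps,
            }
        )
    df = pd.DataFrame(rows)
    if roles is not None:
        df["role"] = df["species"].map(roles)
    return df


def _removal_order(
    deps: DependencyStructure,
    scenario: str,
    roles: dict[str, str] | None,
    rng: np.random.Generator,
) -> list[str]:
    species = deps.species
    if scenario == "random":
        order = list(species)
        rng.shuffle(order)
        return order
    if roles is None:
        raise ValueError(f"scenario {scenario!r} needs a species -> role mapping")
    missing = [sp for sp in species if sp not in roles]
    if missing:
        raise ValueError(f"no role for species {missing[:5]}...")
    role_rank = list(ROLE_ORDER) if scenario == "most-to-least" else list(ROLE_ORDER)[::-1]
    order = []
    for role in role_rank:
        block = [sp for sp in species if roles[sp] == role]
        rng.shuffle(block)  # random order within a role class, redrawn per run
        order.extend(block)
    return order


def sequential_removal(
    deps: DependencyStructure,
    scenario: str,
    roles: dict[str, str] | None = None,
    seed: int | np.random.Generator = 0,
) -> RobustnessCurve:
    """One sequential-removal run; returns the attack curve and its AUC.

    Species are removed one at a time in scenario order; species already
    extinct through coextinction are skipped as primary targets.  The
    x-axis counts primary removals over the initial species number; after
    each removal the cascade runs to equilibrium and y = proportion of
    species remaining is recorded.  When cascades empty the network before
    every species has been a primary target, the curve is closed with a
    terminal (1, 0) point (zero remaining area).  AUC is the trapezoidal
    integral; with no propagation (all R = 0) the curve is y = 1 - x and
    AUC = 0.5 exactly.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    n = deps.n_species
    order = _removal_order(deps, scenario, roles, rng)
    extinct: set[str] = set()
    xs = [0.0]
    ys = [1.0]
    removed = 0
    for sp in order:
        if sp in extinct:
            continue
        removed += 1
        result = _cascade_among(deps, sp, extinct, rng)
        extinct = result
        xs.append(removed / n)
        ys.append((n - len(extinct)) / n)
        if len(extinct) == n:
            break
    if xs[-1] < 1.0:
        xs.append(1.0)
        ys.append(0.0)
    x = np.array(xs)
    y = np.array(ys)
    auc = float(np.trapezoid(y, x))
    return RobustnessCurve(
        scenario=scenario, x=x, y=y, auc=auc, seed=seed if isinstance(seed, int) else None
    )


def _cascade_among(
    deps: DependencyStructure, primary: str, already_extinct: set[str], rng: np.random.Generator
) -> set[str]:
    """Cascade from ``primary`` with part of the network already gone."""
    extinct = set(already_extinct) | {primary}
    newly = [primary]
    while newly:
        next_new: list[str] = []
        doomed: set[str] = set()
        for x in newly:
            for y, _ in sorted(deps.partners[x].items()):
                if y in extinct or y in doomed:
                    continue
                if rng.random() < deps.R[y] * deps.partners[y][x]:
                    doomed.add(y)
                    next_new.append(y)
        extinct.update(doomed)
        newly = next_new
    return extinct


def robustness_experiment(
    deps: DependencyStructure,
    scenario: str,
    roles: dict[str, str] | None = None,
    n_runs: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC sample over ``n_runs`` independent sequential-removal runs."""
    root = np.random.SeedSequence(seed)
    rows = []
    for run, stream in enumerate(root.spawn(n_runs)):
        curve = sequential_removal(deps, scenario, roles, np.random.default_rng(stream))
        rows.append({"run": run, "scenario": scenario, "auc": curve.auc})
    return pd.DataFrame(rows)


def species_role_map(roles_df: pd.DataFrame) -> dict[str, str]:
    """Resolve per-state-node roles to one role per species.

    A plant scored in both layers is ranked by its most connected role
    (network hub > module hub > connector > peripheral): cascades act on
    species, not state nodes.
    """
    rank = {role: i for i, role in enumerate(ROLE_ORDER)}
    best: dict[str, str] = {}
    for sp, role in roles_df[["species", "role"]].itertuples(index=False):
        if sp not in best or rank[role] < rank[best[sp]]:
            best[sp] = role
    return best


def bootstrap_size_control(
    pollination,
    dispersal,
    target_counts: dict[str, int],
    reps: int = 50,
    R_config: float | dict[str, float] = 0.5,
    single_reps: int = 20,
    auc_runs: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Down-sample a large network to target sizes and re-run the experiments.

    Per replicate: sample without replacement ``target_counts[group]``
    species per trophic group, induce the sub-network on the raw counts,
    rebuild all weights and dependences, and record the grand mean
    single-removal E and the mean random-order AUC.  Role-ordered scenarios
    are not re-run (they would require a full modularity + role recomputation
    per replicate); the random scenario needs no roles.

    ``pollination`` / ``dispersal`` are the large network's InteractionTables.
    """
    from .network import InteractionTable, assemble_multilayer

    network = assemble_multilayer(pollination, dispersal)
    pools = {
        "plant": sorted(network.plants),
        "pollinator": sorted(network.pollinators),
        "disperser": sorted(network.dispersers),
    }
    for group, target in target_counts.items():
        if target > len(pools[group]):
            raise ValueError(
                f"target {group} count {target} exceeds available {len(pools[group])}"
            )
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, stream in enumerate(root.spawn(reps)):
        rng = np.random.default_rng(stream)
        keep: set[str] = set()
        for group, pool in pools.items():
            target = target_counts.get(group, len(pool))
            keep.update(rng.choice(pool, size=target, replace=False))
        sub_tables = []
        for table in (pollination, dispersal):
            entries = table.entries
            mask = entries["plant"].isin(keep) & entries["animal"].isin(keep)
            sub_tables.append(
                InteractionTable(
                    state=table.state, layer=table.layer, entries=entries[mask].reset_index(drop=True)
                )
            )
        sub_net = assemble_multilayer(*sub_tables)
        deps = build_dependencies(sub_net, R_config)
        sub_seed = int(rng.integers(2**31))
        e_table = single_removal_experiment(deps, reps=single_reps, seed=sub_seed)
        aucs = robustness_experiment(deps, "random", n_runs=auc_runs, seed=sub_seed)
        rows.append(
            {
                "replicate": rep,
                "n_species": deps.n_species,
                "mean_E": float(e_table["mean_E"].mean()),
                "mean_auc_random": float(aucs["auc"].mean()),
            }
        )
    return pd.DataFrame(rows)
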