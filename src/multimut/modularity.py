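"""Flow-based module detection on the multilayer network and its null model.

Modules are found with the map equation (Infomap): the partition minimizing
the expected description length of a random walk on the weighted network.
The multilayer structure enters through explicit interlayer links — each
plant active in both mutualisms couples its two state nodes with weight
``n_j / L_tot`` — so the walker crosses between pollination and dispersal
only through mediating plants; no relax-rate coupling is used.

The null model shuffles each layer's integer count matrix with the
Patefield algorithm, preserving every species' total interaction count
(row and column marginals), then rebuilds all weights, mirroring how
``r2dtable`` randomizations are adapted to multilayer networks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .network import (
    DISPERSAL,
    POLLINATION,
    InteractionTable,
    MultilayerNetwork,
    assemble_multilayer,
)


def build_state_graph(network: MultilayerNetwork) -> ig.Graph:
    """Flatten the multilayer network into one weighted undirected graph.

    Vertices are state nodes (species, layer); a plant active in both layers
    contributes two vertices joined by its interlayer link.  Vertex
    attributes: ``species``, ``layer``, ``trophic_group``, ``name``.
    """
    vertices: list[tuple[str, str]] = []
    index: dict[tuple[str, str], int] = {}

    def vid(species: str, layer: str) -> int:
        key = (species, layer)
        if key not in index:
            index[key] = len(vertices)
            vertices.append(key)
        return index[key]

    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    for layer, df in network.layers.items():
        for plant, animal, weight in df[["plant", "animal", "weight"]].itertuples(index=False):
            edges.append((vid(plant, layer), vid(animal, layer)))
            weights.append(float(weight))
    for plant, weight in sorted(network.interlayer.items()):
        edges.append((vid(plant, POLLINATION), vid(plant, DISPERSAL)))
        weights.append(float(weight))
    g = ig.Graph(n=len(vertices), edges=edges)
    g.es["weight"] = weights
    g.vs["species"] = [sp for sp, _ in vertices]
    g.vs["layer"] = [layer for _, layer in vertices]
    g.vs["name"] = [f"{sp}__{layer}" for sp, layer in vertices]
    g.vs["trophic_group"] = [network.trophic_group(sp) for sp, _ in vertices]
    return g


@dataclass
class ModulePartition:
    """Assignment of state nodes to modules.

    ``assignments`` has columns ``species``, ``layer``, ``trophic_group``,
    ``module``; module ids are contiguous from 1, ordered by decreasing
    module size.  A plant's two state nodes may sit in different modules.
    """

    assignments: pd.DataFrame
    n_modules: int
    codelength: float
    seed: int

    def module_of(self, species: str, layer: str) -> int:
        sel = self.assignments[
            (self.assignments["species"] == species) & (self.assignments["layer"] == layer)
        ]
        if sel.empty:
            raise KeyError((species, layer))
        return int(sel["module"].iloc[0])


@dataclass
class NullModelResult:
    observed: int
    shuffled: np.ndarray
    p_value: float
    z_score: float

    def to_dict(self) -> dict:
        return {
            "observed_modules": self.observed,
            "n_shuffles": int(len(self.shuffled)),
            "shuffled_mean": float(np.mean(self.shuffled)),
            "shuffled_sd": float(np.std(self.shuffled, ddof=1)),
            "p_value": self.p_value,
            "z_score": self.z_score,
        }


def _relabel_by_size(membership: list[int]) -> list[int]:
    """Relabel module ids 1..K by decreasing size; ties by first appearance."""
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for pos, m in enumerate(membership):
        sizes[m] = sizes.get(m, 0) + 1
        first.setdefault(m, pos)
    order = sorted(sizes, key=lambda m: (-sizes[m], first[m]))
    relabel = {m: i + 1 for i, m in enumerate(order)}
    return [relabel[m] for m in membership]


def detect_modules(
    network: MultilayerNetwork, seed: int = 0, trials: int = 100
) -> ModulePartition:
    """Best-of-``trials`` map-equation partition of the state graph.

    Deterministic given ``seed``: the optimizer's RNG is seeded before the
    run, and the best (lowest codelength) of the internal trials is kept.
    """
    g = build_state_graph(network)
    if g.ecount() == 0:
        raise ValueError("network has no links; cannot detect modules")
    random.seed(seed)
    clustering = g.community_infomap(edge_weights="weight", trials=trials)
    membership = _relabel_by_size(clustering.membership)
    assignments = pd.DataFrame(
        {
            "species": g.vs["species"],
            "layer": g.vs["layer"],
            "trophic_group": g.vs["trophic_group"],
            "module": membership,
        }
    )
    return ModulePartition(
        assignments=assignments,
        n_modules=int(assignments["module"].max()),
        codelength=float(clustering.codelength),
        seed=seed,
    )


def shuffle_layer(table: InteractionTable, rng: np.random.Generator) -> InteractionTable:
    """Patefield-shuffle one layer's count matrix, preserving all marginals."""
    pivot = table.entries.pivot_table(
        index="plant", columns="animal", values="count", fill_value=0, aggfunc="sum"
    )
    rows = pivot.sum(axis=1).to_numpy(dtype=int)
    cols = pivot.sum(axis=0).to_numpy(dtype=int)
    if min(pivot.shape) == 1:
        # a single-row/column table is fully determined by its marginals
        shuffled = pivot.to_numpy(dtype=int)
    else:
        shuffled = stats.random_table(rows, cols).rvs(method="patefield", random_state=rng)
        shuffled = np.asarray(shuffled, dtype=int)
    if (shuffled < 0).any():
        raise RuntimeError("fixed-marginals sampler produced a negative count")
    plants, animals = np.nonzero(shuffled)
    entries = pd.DataFrame(
        {
            "plant": pivot.index.to_numpy()[plants],
            "animal": pivot.columns.to_numpy()[animals],
            "count": shuffled[plants, animals],
        }
    )
    return InteractionTable(state=table.state, layer=table.layer, entries=entries)


def shuffle_multilayer(
    pollination: InteractionTable,
    dispersal: InteractionTable,
    seed: int | np.random.Generator = 0,
) -> MultilayerNetwork:
    """Shuffle both layers independently and reassemble the multilayer network.

    Intralayer and interlayer weights are recomputed from the shuffled
    counts; a shuffle that leaves no plant in both layers yields a valid,
    layer-disconnected network.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    return assemble_multilayer(shuffle_layer(pollination, rng), shuffle_layer(dispersal, rng))


def module_count_null_test(
    pollination: InteractionTable,
    dispersal: InteractionTable,
    n_shuffles: int = 1000,
    seed: int = 0,
    trials: int = 20,
) -> NullModelResult:
    """Two-tailed empirical test of the observed module count.

    ``p = min(1, 2 * min(r_ge + 1, r_le + 1) / (n + 1))`` where ``r_ge`` /
    ``r_le`` count shuffled module counts at least / at most the observed
    value; a z-score against the shuffled distribution is also reported.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    network = assemble_multilayer(pollination, dispersal)
    observed = detect_modules(network, seed=seed, trials=trials).n_modules
    rng = np.random.default_rng(seed)
    shuffled = np.empty(n_shuffles, dtype=int)
    for i in range(n_shuffles):
        net_i = shuffle_multilayer(pollination, dispersal, rng)
        shuffled[i] = detect_modules(net_i, seed=seed + i + 1, trials=trials).n_modules
    r_ge = int(np.sum(shuffled >= observed))
    r_le = int(np.sum(shuffled <= observed))
    p = min(1.0, 2.0 * min(r_ge + 1, r_le + 1) / (n_shuffles + 1))
    sd = float(np.std(shuffled, ddof=1))
    z = float((observed - np.mean(shuffled)) / sd) if sd > 0 else float("inf")
    return NullModelResult(observed=observed, shuffled=shuffled, p_value=p, z_score=z)


def module_layer_summary(partition: ModulePartition) -> pd.DataFrame:
    """Occupancy of each module in each layer, as counts and proportions.

    Proportions are of the network's state nodes, so they sum to 1 over all
    (module, layer) cells; modules are ordered by decreasing size.
    """
    df = partition.assignments
    total = len(df)
    occ = (
        df.groupby(["module", "layer"], sort=True).size().reset_index(name="n_state_nodes")
    )
    occ["proportion"] = occ["n_state_nodes"] / total
    module_sizes = df.groupby("module").size()
    occ["module_size"] = occ["module"].map(module_sizes)
    occ = occ.sort_values(
        ["module_size", "module", "layer"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return occ[["module", "layer", "n_state_nodes", "proportion", "module_size"]]
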