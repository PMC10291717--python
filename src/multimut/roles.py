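"""Structural species roles from the module partition (z-c framework).

Each state node gets a within-module degree ``z`` (its number of links to
members of its own module, standardized over that module) and an
among-module connectivity ``c`` (participation coefficient,
``1 - sum_m (k_m / k)^2``).  The (z, c) plane is split into four roles with
the thresholds z = 2.5 and c = 0.62, boundaries inclusive on <=:

==============  =========  ==========
role            z          c
==============  =========  ==========
peripheral      <= 2.5     <= 0.62
connector       <= 2.5     >  0.62
module hub      >  2.5     <= 0.62
network hub     >  2.5     >  0.62
==============  =========  ==========

Degrees are binary (link presence) on the same flattened multilayer graph
used for module detection, so a plant active in both mutualisms has two
state nodes — each scored independently — and its interlayer self-link
counts as one link between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .modularity import ModulePartition, build_state_graph
from .network import MultilayerNetwork

PERIPHERAL = "peripheral"
CONNECTOR = "connector"
MODULE_HUB = "module hub"
NETWORK_HUB = "network hub"
ROLE_ORDER = (NETWORK_HUB, MODULE_HUB, CONNECTOR, PERIPHERAL)  # most to least connected

Z_THRESHOLD = 2.5
C_THRESHOLD = 0.62


def classify_role(z: float, c: float) -> str:
    """Map a (z, c) point to its role; thresholds inclusive on <=."""
    if z <= Z_THRESHOLD:
        return PERIPHERAL if c <= C_THRESHOLD else CONNECTOR
    return MODULE_HUB if c <= C_THRESHOLD else NETWORK_HUB


def participation_coefficient(links_per_module: dict[int, int]) -> float:
    """``c = 1 - sum_m (k_m / k)^2``; 0 for an isolated node by convention."""
    k = sum(links_per_module.values())
    if k == 0:
        return 0.0
    return 1.0 - sum((km / k) ** 2 for km in links_per_module.values())


def within_module_z(k_in: np.ndarray) -> np.ndarray:
    """Standardize within-module degrees over one module's members.

    Uses the population SD of the module members' k_in; a module whose
    members all have the same k_in gets z = 0 for every member.
    """
    k_in = np.asarray(k_in, dtype=float)
    sd = k_in.std()
    if sd == 0:
        return np.zeros_like(k_in)
    return (k_in - k_in.mean()) / sd


def assign_roles(
    network: MultilayerNetwork, partition: ModulePartition, weighted: bool = False
) -> pd.DataFrame:
    """Compute z, c and the categorical role for every state node.

    Parameters
    ----------
    weighted
        If True, degrees use link weights instead of link presence — an
        optional diagnostic; the standard role taxonomy is binary.

    Returns a DataFrame with columns ``species, layer, trophic_group,
    module, z, c, role``, aligned with the partition's state nodes.
    """
    g = build_state_graph(network)
    module_by_key = {
        (sp, layer): int(m)
        for sp, layer, m in partition.assignments[["species", "layer", "module"]].itertuples(
            index=False
        )
    }
    modules = np.array(
        [module_by_key[(v["species"], v["layer"])] for v in g.vs], dtype=int
    )
    n = g.vcount()
    k_in = np.zeros(n)
    per_module: list[dict[int, float]] = [dict() for _ in range(n)]
    for e in g.es:
        u, v = e.tuple
        w = float(e["weight"]) if weighted else 1.0
        per_module[u][modules[v]] = per_module[u].get(modules[v], 0.0) + w
        per_module[v][modules[u]] = per_module[v].get(modules[u], 0.0) + w
        if modules[u] == modules[v]:
            k_in[u] += w
            k_in[v] += w
    z = np.zeros(n)
    for m in np.unique(modules):
        members = np.nonzero(modules == m)[0]
        z[members] = within_module_z(k_in[members])
    c = np.array([participation_coefficient(pm) for pm in per_module])
    df = pd.DataFrame(
        {
            "species": g.vs["species"],
            "layer": g.vs["layer"],
            "trophic_group": g.vs["trophic_group"],
            "module": modules,
            "z": z,
            "c": c,
        }
    )
    df["role"] = [classify_role(zi, ci) for zi, ci in zip(df["z"], df["c"])]
    return df.sort_values(["layer", "species"]).reset_index(drop=True)


def role_percentages(roles: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each role, over state nodes and over physical species.

    Plants active in both layers carry two role assignments; the state-node
    tally counts both, the per-species tally resolves each species to its
    most connected role.
    """
    by_state = roles["role"].value_counts(normalize=True) * 100
    rank = {role: i for i, role in enumerate(ROLE_ORDER)}
    best = roles.sort_values("role", key=lambda s: s.map(rank)).drop_duplicates("species")
    by_species = best["role"].value_counts(normalize=True) * 100
    return pd.DataFrame(
        {
            "role": list(ROLE_ORDER),
            "pct_state_nodes": [float(by_state.get(r, 0.0)) for r in ROLE_ORDER],
            "pct_species": [float(by_species.get(r, 0.0)) for r in ROLE_ORDER],
        }
    )


def _transition_group(trophic_group: str, layer: str) -> str:
    if trophic_group == "plant":
        return f"plant ({layer})"
    return trophic_group


def role_transitions(roles_a: pd.DataFrame, roles_b: pd.DataFrame) -> pd.DataFrame:
    """Tally role changes between two states for shared state nodes.

    Groups are pollinators, dispersers, plants in the pollination layer and
    plants in the dispersal layer; only (species, layer) state nodes present
    in both assignments are counted, self-transitions included.
    """
    a = roles_a.set_index(["species", "layer"])
    b = roles_b.set_index(["species", "layer"])
    shared = a.index.intersection(b.index)
    records: dict[tuple[str, str, str], int] = {}
    for key in shared:
        group = _transition_group(a.loc[key, "trophic_group"], key[1])
        pair = (group, a.loc[key, "role"], b.loc[key, "role"])
        records[pair] = records.get(pair, 0) + 1
    return pd.DataFrame(
        [(g, r_from, r_to, n) for (g, r_from, r_to), n in sorted(records.items())],
        columns=["group", "role_from", "role_to", "n_species"],
    )
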