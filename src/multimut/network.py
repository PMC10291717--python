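"""Construction of the weighted multilayer pollination-seed-dispersal network.

A community is observed as two bipartite interaction layers that share plant
nodes: a pollination layer (plant x pollinator visit counts) and a seed
dispersal layer (plant x frugivore feeding counts).  The two layers are
coupled into one multilayer network through the plants active in both
mutualisms:

* intralayer link weight  ``w_ji = f_ji / V``  where ``f_ji`` is the raw
  count for the (plant j, animal i) pair and ``V`` the layer's total count,
  so each layer's weights sum to 1;
* an *indirect link* is a pollinator-disperser species pair connected by a
  two-step walk through a shared plant;
* interlayer link weight  ``w_j = n_j / L_tot``  where ``n_j`` is the number
  of indirect links mediated by plant ``j`` and ``L_tot`` their total, an
  undirected self-link coupling the plant's two state nodes.

Both link types live on the same [0, 1] scale so that downstream flow-based
analyses are not biased toward either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

POLLINATION = "pollination"
DISPERSAL = "dispersal"
LAYERS = (POLLINATION, DISPERSAL)

#: trophic group labels
PLANT = "plant"
POLLINATOR = "pollinator"
DISPERSER = "disperser"

EDGE_COLUMNS = ("state", "layer", "plant", "animal", "count")


class FormatError(ValueError):
    """Input file does not have the expected tabular layout."""


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class EmptyLayerError(ValueError):
    """A layer has zero total interaction count."""


@dataclass(frozen=True)
class InteractionTable:
    """Raw interaction counts for one layer of one network state.

    ``entries`` has columns ``plant``, ``animal``, ``count`` with positive
    integer counts and no duplicated (plant, animal) pair.
    """

    state: str
    layer: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        if list(df.columns) != ["plant", "animal", "count"]:
            raise FormatError(
                f"entries must have columns plant, animal, count; got {list(df.columns)}"
            )
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        counts = df["count"]
        if len(df):
            if (counts <= 0).any():
                raise ValidationError("counts must be positive (zero rows are dropped at read time)")
            if not (counts == counts.astype(int)).all():
                raise ValidationError("counts must be integers")
            if df.duplicated(subset=["plant", "animal"]).any():
                dup = df[df.duplicated(subset=["plant", "animal"], keep=False)]
                raise ValidationError(
                    f"duplicate (plant, animal) pairs within layer {self.layer}: "
                    f"{sorted(set(map(tuple, dup[['plant', 'animal']].values)))}"
                )
            if (df["plant"].astype(str) == "").any() or (df["animal"].astype(str) == "").any():
                raise ValidationError("species ids must be non-empty")

    @property
    def plants(self) -> set[str]:
        return set(self.entries["plant"])

    @property
    def animals(self) -> set[str]:
        return set(self.entries["animal"])

    @property
    def total(self) -> int:
        return int(self.entries["count"].sum())


@dataclass
class MultilayerNetwork:
    """Two weighted bipartite layers sharing plants, plus interlayer self-links.

    Attributes
    ----------
    state
        Community state label (e.g. ``intact`` or ``invaded``).
    layers
        Mapping layer name -> DataFrame with columns ``plant``, ``animal``,
        ``count``, ``weight``; weights in each layer sum to 1.
    interlayer
        Mapping plant id -> interlayer weight ``n_j / L_tot``; sums to 1
        whenever at least one plant occurs in both layers.
    n_indirect
        Mapping plant id -> number of distinct pollinator-disperser pairs
        it mediates (``n_j = p_j * d_j``).
    """

    state: str
    layers: dict[str, pd.DataFrame]
    interlayer: dict[str, float]
    n_indirect: dict[str, int]
    l_tot: int
    layer_disconnected: bool = field(default=False)

    @property
    def plants(self) -> set[str]:
        return set().union(*(set(df["plant"]) for df in self.layers.values()))

    @property
    def pollinators(self) -> set[str]:
        return set(self.layers[POLLINATION]["animal"])

    @property
    def dispersers(self) -> set[str]:
        return set(self.layers[DISPERSAL]["animal"])

    @property
    def interlayer_plants(self) -> set[str]:
        return set(self.interlayer)

    @property
    def n_species(self) -> int:
        return len(self.plants) + len(self.pollinators) + len(self.dispersers)

    def trophic_group(self, species: str) -> str:
        if species in self.plants:
            return PLANT
        if species in self.pollinators:
            return POLLINATOR
        if species in self.dispersers:
            return DISPERSER
        raise KeyError(species)

    def summary(self) -> dict:
        return {
            "state": self.state,
            "n_plants": len(self.plants),
            "n_pollinators": len(self.pollinators),
            "n_dispersers": len(self.dispersers),
            "n_species": self.n_species,
            "n_interlayer_plants": len(self.interlayer),
            "interlayer_plants": sorted(self.interlayer),
            "l_tot": self.l_tot,
            "layer_disconnected": self.layer_disconnected,
        }


def read_interactions(path: str | Path) -> dict[tuple[str, str], InteractionTable]:
    """Read a comma-delimited edge list into one table per (state, layer).

    Expected columns: ``state, layer, plant, animal, count``.  Rows with a
    zero count are observation placeholders and are dropped.
    """
    df = pd.read_csv(path, dtype={"plant": str, "animal": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    if len(df):
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any() or (counts < 0).any() or not (counts == counts.astype(int)).all():
            raise ValidationError(f"counts must be non-negative integers in {path}")
        df = df.assign(count=counts.astype(int))
        df = df[df["count"] > 0]
    tables: dict[tuple[str, str], InteractionTable] = {}
    for (state, layer), grp in df.groupby(["state", "layer"], sort=True):
        entries = grp[["plant", "animal", "count"]].reset_index(drop=True)
        tables[(state, layer)] = InteractionTable(state=state, layer=layer, entries=entries)
    return tables


def normalize_intralayer(table: InteractionTable) -> pd.DataFrame:
    """Return the table's entries with a ``weight`` column, ``w = f / V``."""
    total = table.total
    if total <= 0:
        raise EmptyLayerError(f"layer {table.layer} of state {table.state} has zero total count")
    df = table.entries.copy()
    df["weight"] = df["count"] / total
    return df


def enumerate_indirect_links(
    layer_a: InteractionTable, layer_b: InteractionTable
) -> tuple[list[tuple[str, str, str]], dict[str, int], int]:
    """Enumerate pollinator-disperser pairs mediated by shared plants.

    For every plant present in both layers with ``p`` pollinator partners and
    ``d`` disperser partners there are ``n_j = p * d`` indirect links, each a
    distinct (pollinator, disperser) species pair mediated by that plant.

    Returns the (pollinator, disperser, plant) triples, ``n_j`` per plant and
    ``L_tot``.
    """
    partners_a: dict[str, list[str]] = {}
    for plant, animal in layer_a.entries[["plant", "animal"]].itertuples(index=False):
        partners_a.setdefault(plant, []).append(animal)
    links: list[tuple[str, str, str]] = []
    n_indirect: dict[str, int] = {}
    for plant, grp in layer_b.entries.groupby("plant", sort=True):
        if plant not in partners_a:
            continue
        dispersers = list(grp["animal"])
        pollinators = sorted(partners_a[plant])
        n_indirect[plant] = len(pollinators) * len(dispersers)
        for pol in pollinators:
            for disp in sorted(dispersers):
                links.append((pol, disp, plant))
    return links, n_indirect, sum(n_indirect.values())


def compute_interlayer_weights(n_indirect: dict[str, int], l_tot: int) -> dict[str, float]:
    """``w_j = n_j / L_tot``; empty when no plant couples the layers."""
    if l_tot <= 0:
        return {}
    return {plant: n / l_tot for plant, n in n_indirect.items()}


def assemble_multilayer(
    pollination: InteractionTable, dispersal: InteractionTable
) -> MultilayerNetwork:
    """Build the full multilayer network for one community state."""
    if pollination.state != dispersal.state:
        raise ValidationError(
            f"layer states differ: {pollination.state!r} vs {dispersal.state!r}"
        )
    if pollination.layer != POLLINATION or dispersal.layer != DISPERSAL:
        raise ValidationError("tables must be the pollination and dispersal layers, in that order")
    plants = pollination.plants | dispersal.plants
    animals = pollination.animals | dispersal.animals
    shared = plants & animals
    if shared:
        raise ValidationError(f"species appear as both plant and animal: {sorted(shared)}")
    layers = {
        POLLINATION: normalize_intralayer(pollination),
        DISPERSAL: normalize_intralayer(dispersal),
    }
    _, n_indirect, l_tot = enumerate_indirect_links(pollination, dispersal)
    interlayer = compute_interlayer_weights(n_indirect, l_tot)
    return MultilayerNetwork(
        state=pollination.state,
        layers=layers,
        interlayer=interlayer,
        n_indirect=n_indirect,
        l_tot=l_tot,
        layer_disconnected=l_tot == 0,
    )


def write_multilayer(network: MultilayerNetwork, outdir: str | Path) -> dict[str, Path]:
    """Serialize a network: multilayer edge list, node table, JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for layer, df in network.layers.items():
        for plant, animal, count, weight in df[["plant", "animal", "count", "weight"]].itertuples(
            index=False
        ):
            rows.append((layer, plant, layer, animal, count, weight))
    for plant, weight in sorted(network.interlayer.items()):
        rows.append((POLLINATION, plant, DISPERSAL, plant, network.n_indirect[plant], weight))
    edges = pd.DataFrame(
        rows, columns=["layer_from", "node_from", "layer_to", "node_to", "count", "weight"]
    )
    nodes = pd.DataFrame(
        sorted(
            [(sp, PLANT) for sp in network.plants]
            + [(sp, POLLINATOR) for sp in network.pollinators]
            + [(sp, DISPERSER) for sp in network.dispersers]
        ),
        columns=["node", "trophic_group"],
    )
    paths = {
        "edges": outdir / f"{network.state}_multilayer_edges.csv",
        "nodes": outdir / f"{network.state}_nodes.csv",
        "summary": outdir / f"{network.state}_network_summary.json",
    }
    edges.to_csv(paths["edges"], index=False)
    nodes.to_csv(paths["nodes"], index=False)
    paths["summary"].write_text(json.dumps(network.summary(), indent=2))
    return paths


def read_multilayer(edges_path: str | Path, state: str) -> MultilayerNetwork:
    """Rebuild a network from the edge list written by :func:`write_multilayer`.

    Weights round-trip bit-for-bit: they are re-derived from the integer
    counts with the same arithmetic used at assembly time.
    """
    edges = pd.read_csv(edges_path, dtype={"node_from": str, "node_to": str})
    tables = {}
    for layer in LAYERS:
        intra = edges[(edges["layer_from"] == layer) & (edges["layer_to"] == layer)]
        entries = intra[["node_from", "node_to", "count"]].rename(
            columns={"node_from": "plant", "node_to": "animal"}
        )
        entries = entries.astype({"count": int}).reset_index(drop=True)
        tables[layer] = InteractionTable(state=state, layer=layer, entries=entries)
    return assemble_multilayer(tables[POLLINATION], tables[DISPERSAL])
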