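"""Connectivity between the pollination and seed-dispersal mutualisms.

The coupling between the two interaction types is summarized at three
levels: which plants mediate it (interlayer plants and their weights), how
many pollinator-disperser species pairs are connected through at least one
shared plant (the binary indirect-link matrix), and how much the identity of
those pairs turns over between two community states (Jaccard dissimilarity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DISPERSER, POLLINATOR, MultilayerNetwork


@dataclass
class IndirectLinkMatrix:
    """Binary pollinator x disperser matrix; 1 iff the pair shares >=1 plant."""

    matrix: pd.DataFrame  # index: pollinators, columns: dispersers, values {0,1}

    @property
    def pollinators(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def dispersers(self) -> list[str]:
        return list(self.matrix.columns)

    def pairs(self) -> set[tuple[str, str]]:
        """The set of connected (pollinator, disperser) species pairs."""
        rows, cols = np.nonzero(self.matrix.values)
        return {
            (self.matrix.index[r], self.matrix.columns[c]) for r, c in zip(rows, cols)
        }


def indirect_link_matrix(network: MultilayerNetwork) -> IndirectLinkMatrix:
    """Entry (i, k) = 1 iff some plant links pollinator i and disperser k."""
    pollinators = sorted(network.pollinators)
    dispersers = sorted(network.dispersers)
    mat = pd.DataFrame(0, index=pollinators, columns=dispersers, dtype=int)
    pol_by_plant = network.layers["pollination"].groupby("plant")["animal"].apply(set)
    disp_by_plant = network.layers["dispersal"].groupby("plant")["animal"].apply(set)
    for plant in set(pol_by_plant.index) & set(disp_by_plant.index):
        for pol in pol_by_plant[plant]:
            for disp in disp_by_plant[plant]:
                mat.loc[pol, disp] = 1
    return IndirectLinkMatrix(matrix=mat)


def per_species_indirect_stats(ilm: IndirectLinkMatrix) -> pd.DataFrame:
    """Per-animal indirect-link counts and proportions.

    The proportion divides by the number of potential partners in the
    opposite trophic group of the same network, making values comparable
    between networks of different size.
    """
    records = []
    n_disp = len(ilm.dispersers)
    n_pol = len(ilm.pollinators)
    row_sums = ilm.matrix.sum(axis=1)
    col_sums = ilm.matrix.sum(axis=0)
    for sp in ilm.pollinators:
        count = int(row_sums[sp])
        records.append((sp, POLLINATOR, count, count / n_disp if n_disp else np.nan))
    for sp in ilm.dispersers:
        count = int(col_sums[sp])
        records.append((sp, DISPERSER, count, count / n_pol if n_pol else np.nan))
    return pd.DataFrame(records, columns=["species", "trophic_group", "count", "proportion"])


def group_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and SE (sd / sqrt(n)) of indirect-link counts per trophic group."""
    rows = []
    for group, grp in stats.groupby("trophic_group", sort=True):
        counts = grp["count"].to_numpy(dtype=float)
        n = len(counts)
        sd = float(np.std(counts, ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "trophic_group": group,
                "n_species": n,
                "mean_count": float(np.mean(counts)) if n else np.nan,
                "sd_count": sd,
                "se_count": sd / math.sqrt(n) if n else np.nan,
                "mean_proportion": float(grp["proportion"].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def interlayer_plant_presence(
    network_a: MultilayerNetwork, network_b: MultilayerNetwork
) -> pd.DataFrame:
    """Presence/absence of an interlayer link per plant in each state."""
    plants = sorted(network_a.plants | network_b.plants)
    return pd.DataFrame(
        {
            "plant": plants,
            network_a.state: [int(p in network_a.interlayer) for p in plants],
            network_b.state: [int(p in network_b.interlayer) for p in plants],
        }
    )


def indirect_link_turnover(
    ilm_a: IndirectLinkMatrix, ilm_b: IndirectLinkMatrix
) -> float:
    """Jaccard dissimilarity of the connected pair sets of two networks.

    ``J = 1 - |A ∩ B| / |A ∪ B]`` over species-identity pairs taken across
    the union of both networks' species pools.  Returns NaN when both pair
    sets are empty.
    """
    pairs_a = ilm_a.pairs()
    pairs_b = ilm_b.pairs()
    union = pairs_a | pairs_b
    if not union:
        return float("nan")
    return 1.0 - len(pairs_a & pairs_b) / len(union)


def connectivity_summary(network: MultilayerNetwork) -> dict:
    """Headline connectivity quantities for one network state."""
    ilm = indirect_link_matrix(network)
    stats = per_species_indirect_stats(ilm)
    groups = group_summary(stats)
    return {
        "state": network.state,
        "n_interlayer_plants": len(network.interlayer),
        "interlayer_weights": dict(sorted(network.interlayer.items())),
        "l_tot": network.l_tot,
        "group_summary": groups.to_dict(orient="records"),
    }
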