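"""Synthetic plant-pollinator-disperser communities.

The generator emulates the statistical signature of temperate-forest
mutualistic visitation data: heavy-tailed species activities (log-normal
species effects — a few generalists, many rare specialists), Poisson
counting noise around activity products, a pollination layer much larger
than the dispersal layer, few broadly connected dispersers, and a
configurable fraction of plants active in both mutualisms (the interlayer
plants).  Two shipped presets mirror the magnitudes of an intact community
(37 plants, 95 pollinators, 4 dispersers, ~22% interlayer plants) and an
ungulate-invaded one (24 plants, 67 pollinators, 4 dispersers, ~21%).

Optionally a planted block structure partitions each layer's species into
well-separated modules, for calibrating module-detection recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import DISPERSAL, POLLINATION, InteractionTable


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of one synthetic community state.

    ``activity_sigma`` is the SD of log-activity (log-normal species
    effects); ``events_*`` are expected total interaction events per layer;
    ``interlayer_fraction`` is the fraction of plants designated to occur in
    both layers; ``n_dispersal_only_plants`` adds plants found only in the
    dispersal layer (fleshy-fruited species never observed in flower).
    ``modules_per_layer`` > 0 plants a block structure with between-block
    rates damped by ``block_epsilon``.
    """

    name: str = "community"
    n_plants: int = 37
    n_pollinators: int = 95
    n_dispersers: int = 4
    interlayer_fraction: float = 0.22
    n_dispersal_only_plants: int = 2
    activity_sigma: float = 1.0
    events_pollination: int = 1200
    events_dispersal: int = 400
    modules_per_layer: int = 0
    block_epsilon: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_plants, self.n_pollinators, self.n_dispersers) < 1:
            raise ValueError("species counts must be >= 1")
        if not 0.0 <= self.interlayer_fraction <= 1.0:
            raise ValueError("interlayer_fraction must lie in [0, 1]")
        if self.n_dispersal_only_plants >= self.n_plants:
            raise ValueError("dispersal-only plants must leave room for pollinated plants")
        n_disp_plants = self.n_interlayer_plants + self.n_dispersal_only_plants
        if self.events_pollination < self.n_plants + self.n_pollinators or (
            n_disp_plants > 0 and self.events_dispersal < n_disp_plants + self.n_dispersers
        ):
            raise ValueError("expected events must be at least the species counts per layer")
        if self.interlayer_fraction == 1.0 and self.events_dispersal == 0:
            raise ValueError("interlayer fraction 1 with zero dispersal events is infeasible")

    @property
    def n_interlayer_plants(self) -> int:
        return round(self.interlayer_fraction * self.n_plants)


def _species_ids(prefix: str, n: int, offset: int = 0) -> list[str]:
    return [f"{prefix}{i + offset:03d}" for i in range(1, n + 1)]


def _sample_layer(
    plants: list[str],
    animals: list[str],
    events: int,
    sigma: float,
    k_blocks: int,
    epsilon: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson counts around log-normal activity products, optional blocks."""
    a_plant = rng.lognormal(0.0, sigma, len(plants))
    a_animal = rng.lognormal(0.0, sigma, len(animals))
    rate = np.outer(a_plant, a_animal)
    if k_blocks > 1:
        block_p = rng.integers(k_blocks, size=len(plants))
        block_a = rng.integers(k_blocks, size=len(animals))
        damp = np.where(block_p[:, None] == block_a[None, :], 1.0, epsilon)
        rate = rate * damp
    rate *= events / rate.sum()
    counts = rng.poisson(rate)
    # every configured species must realize >=1 interaction in its layer
    for i in np.nonzero(counts.sum(axis=1) == 0)[0]:
        j = rng.choice(len(animals), p=rate[i] / rate[i].sum())
        counts[i, j] += 1
    for j in np.nonzero(counts.sum(axis=0) == 0)[0]:
        i = rng.choice(len(plants), p=rate[:, j] / rate[:, j].sum())
        counts[i, j] += 1
    rows, cols = np.nonzero(counts)
    return pd.DataFrame(
        {
            "plant": np.array(plants)[rows],
            "animal": np.array(animals)[cols],
            "count": counts[rows, cols],
        }
    ).sort_values(["plant", "animal"]).reset_index(drop=True)


def generate_community(
    config: CommunityConfig,
    species_pool: dict[str, list[str]] | None = None,
) -> tuple[InteractionTable, InteractionTable]:
    """Generate the (pollination, dispersal) table pair for one state.

    Deterministic given ``config.seed``.  ``species_pool`` optionally fixes
    the id lists (keys ``plants``, ``pollinators``, ``dispersers``) so that
    two states can share species identities.
    """
    rng = np.random.default_rng(config.seed)
    if species_pool is None:
        plants = _species_ids("P", config.n_plants)
        pollinators = _species_ids("A", config.n_pollinators)
        dispersers = _species_ids("D", config.n_dispersers)
    else:
        plants = list(species_pool["plants"])
        pollinators = list(species_pool["pollinators"])
        dispersers = list(species_pool["dispersers"])
    n_inter = config.n_interlayer_plants
    interlayer_plants = plants[:n_inter]
    pollination_plants = plants[: config.n_plants - config.n_dispersal_only_plants]
    dispersal_plants = interlayer_plants + plants[len(pollination_plants):]
    if not dispersal_plants:  # no plant feeds the dispersal layer: give it the rarest plant
        dispersal_plants = plants[-1:]
    pol_entries = _sample_layer(
        pollination_plants,
        pollinators,
        config.events_pollination,
        config.activity_sigma,
        config.modules_per_layer,
        config.block_epsilon,
        rng,
    )
    disp_entries = _sample_layer(
        dispersal_plants,
        dispersers,
        config.events_dispersal,
        config.activity_sigma,
        config.modules_per_layer,
        config.block_epsilon,
        rng,
    )
    return (
        InteractionTable(state=config.name, layer=POLLINATION, entries=pol_entries),
        InteractionTable(state=config.name, layer=DISPERSAL, entries=disp_entries),
    )


def generate_state_pair(
    intact_config: CommunityConfig,
    invaded_config: CommunityConfig,
    overlap_fraction: float = 0.8,
    seed: int | None = None,
) -> dict[str, tuple[InteractionTable, InteractionTable]]:
    """Two community states with partially shared species pools.

    A fraction ``overlap_fraction`` of the (smaller) second state's species
    in each trophic group carries the same ids as in the first state; the
    rest are state-specific.  Shared ids are taken from the head of each
    pool so interlayer plants tend to be shared, as in the field system.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    intact_pool = {
        "plants": _species_ids("P", intact_config.n_plants),
        "pollinators": _species_ids("A", intact_config.n_pollinators),
        "dispersers": _species_ids("D", intact_config.n_dispersers),
    }
    counts = {
        "plants": invaded_config.n_plants,
        "pollinators": invaded_config.n_pollinators,
        "dispersers": invaded_config.n_dispersers,
    }
    prefixes = {"plants": "Px", "pollinators": "Ax", "dispersers": "Dx"}
    invaded_pool = {}
    for group, n in counts.items():
        n_shared = round(overlap_fraction * n)
        n_shared = min(n_shared, len(intact_pool[group]))
        fresh = _species_ids(prefixes[group], n - n_shared, offset=1000)
        invaded_pool[group] = intact_pool[group][:n_shared] + fresh
    if seed is not None:
        intact_config = replace_seed(intact_config, seed)
        invaded_config = replace_seed(invaded_config, seed + 1)
    return {
        intact_config.name: generate_community(intact_config, intact_pool),
        invaded_config.name: generate_community(invaded_config, invaded_pool),
    }


def replace_seed(config: CommunityConfig, seed: int) -> CommunityConfig:
    from dataclasses import replace

    return replace(config, seed=seed)


def load_preset(name: str, **overrides) -> CommunityConfig:
    """Load a shipped preset (``intact_like`` or ``invaded_like``)."""
    ref = resources.files("multimut.presets") / f"{name}.yaml"
    try:
        payload = yaml.safe_load(ref.read_text())
    except FileNotFoundError:
        raise KeyError(f"no preset named {name!r}") from None
    payload.update(overrides)
    return CommunityConfig(**payload)


def write_edge_list(
    tables: dict[str, tuple[InteractionTable, InteractionTable]], path: str | Path
) -> Path:
    """Write generated states as the edge-list format the reader accepts."""
    rows = []
    for _, pair in sorted(tables.items()):
        for table in pair:
            for plant, animal, count in table.entries.itertuples(index=False):
                rows.append((table.state, table.layer, plant, animal, count))
    df = pd.DataFrame(rows, columns=["state", "layer", "plant", "animal", "count"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path
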