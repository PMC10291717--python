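import pandas as pd
import pytest

from multimut.network import (
    DISPERSAL,
    POLLINATION,
    InteractionTable,
    assemble_multilayer,
)
from multimut.synthetic import generate_state_pair, load_preset


def make_table(state, layer, rows):
    """rows: list of (plant, animal, count)."""
    return InteractionTable(
        state=state,
        layer=layer,
        entries=pd.DataFrame(rows, columns=["plant", "animal", "count"]),
    )


@pytest.fixture
def toy_tables():
    """Two plants; pA couples the layers (2 pollinators x 1 disperser)."""
    pol = make_table("toy", POLLINATION, [("pA", "pol1", 3), ("pA", "pol2", 1), ("pB", "pol1", 4)])
    disp = make_table("toy", DISPERSAL, [("pA", "disp1", 2), ("pC", "disp1", 1)])
    return pol, disp


@pytest.fixture
def toy_network(toy_tables):
    return assemble_multilayer(*toy_tables)


@pytest.fixture(scope="session")
def preset_pair():
    """Intact-like / invaded-like synthetic state pair at the shipped presets."""
    return generate_state_pair(
        load_preset("intact_like"), load_preset("invaded_like"), overlap_fraction=0.8, seed=11
    )


@pytest.fixture(scope="session")
def preset_networks(preset_pair):
    return {state: assemble_multilayer(pol, disp) for state, (pol, disp) in preset_pair.items()}
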