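import numpy as np
import pytest

from hergcycle import herg1_model as hm
from hergcycle.reaction_engine import ParameterSet, Reaction, ReactionNetwork, Species


@pytest.fixture(scope="session")
def herg_network():
    return hm.default_network()


@pytest.fixture(scope="session")
def hek_params():
    return hm.published_parameters("HEK-hERG1")


@pytest.fixture(scope="session")
def hek_basal(herg_network, hek_params):
    return hm.initial_state(hek_params, seeding=False, network=herg_network)


@pytest.fixture(scope="session")
def hek_seeded(herg_network, hek_params, hek_basal):
    seeded = hek_basal.copy()
    seeded[herg_network.species_index("F")] += (
        (1.0 - hek_params["phi0"]) * hek_params["F0"]
    )
    return seeded


@pytest.fixture
def decay_network():
    """Single first-order decay M -> 0."""
    return ReactionNetwork(
        [Species("M", initial_default=1000.0)],
        [Reaction("decay", {"M": 1}, {}, {}, "k_dm")],
    )


@pytest.fixture
def decay_params():
    return ParameterSet({"k_dm": 0.105}, {"k_dm": "s^-1"}, {"k_dm": True})


@pytest.fixture
def birth_death_network():
    """Constant production plus first-order decay: M* = s/k."""
    return ReactionNetwork(
        [Species("M")],
        [
            Reaction("birth", {}, {"M": 1}, {}, "s"),
            Reaction("death", {"M": 1}, {}, {}, "k"),
        ],
    )
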