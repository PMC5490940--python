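import networkx as nx
import pytest

from polypharm import synthetic_data as sd
from polypharm.interactome import influence_matrix


@pytest.fixture(scope="session")
def edge_graph():
    """The 2-node single-edge graph with a known closed-form kernel."""
    g = nx.Graph()
    g.add_edge("a", "b")
    return g


@pytest.fixture(scope="session")
def two_star_graph():
    """Two 6-leaf stars whose hubs are joined by a 2-node path.

    Heating both hubs reaches both halves of the network; heating either
    hub alone leaves the far star cold, so the hub pair has an advantage.
    """
    g = nx.Graph()
    for i in range(6):
        g.add_edge("h1", f"a{i}")
        g.add_edge("h2", f"b{i}")
    g.add_edge("h1", "m1")
    g.add_edge("m1", "m2")
    g.add_edge("m2", "h2")
    return g


@pytest.fixture(scope="session")
def small_interactome():
    return sd.gen_interactome(100, 4, rng_seed=1)


@pytest.fixture(scope="session")
def planted_module(small_interactome):
    return sd.plant_seed_module(small_interactome, 8, extra_edge_prob=0.6, rng_seed=2)


@pytest.fixture(scope="session")
def toy_models():
    return sd.gen_toy_models(rng_seed=0)


@pytest.fixture(scope="session")
def edge_F(edge_graph):
    return influence_matrix(edge_graph, beta=0.5)
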