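import networkx as nx
import pytest

from pdcim.io_formats import CuratedAssociationSet, OccurrenceProfile
from pdcim.synthetic import worked_toy


@pytest.fixture
def toy_profile():
    """3 incidences over 2 side effects x 2 drugs."""
    return OccurrenceProfile.from_pairs([("se1", "dA"), ("se1", "dB"), ("se2", "dA")])


@pytest.fixture
def triangle():
    """Weighted triangle used across path/cohesiveness tests."""
    g = nx.Graph()
    g.add_edge("a", "b", weight=0.6)
    g.add_edge("b", "c", weight=0.8)
    g.add_edge("a", "c", weight=0.9)
    return g


@pytest.fixture
def toy_pair():
    """The 4-drug x 4-disease worked module pair with 5 curated links."""
    return worked_toy()


@pytest.fixture
def curated_small():
    return CuratedAssociationSet(
        {
            ("d1", "x1"): "T",
            ("d1", "x2"): "M",
            ("d2", "x1"): "M&T",
            ("d3", "x3"): "inferred",
        }
    )


def random_weighted_graph(rng, n_nodes, edge_prob=0.5):
    """Erdos-Renyi graph with U(0.1, 1.0) weights, deterministic given rng."""
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                g.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(0.1, 1.0)))
    return g
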