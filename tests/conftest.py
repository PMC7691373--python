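import pytest

from pmil import BipartiteGraph, project_weighted

from helpers import random_bipartite


@pytest.fixture
def toy_graph():
    """5 + 5 affiliation graph with a mix of shared and unique neighbours."""
    edges = [
        ("A", "h"), ("A", "i"), ("B", "h"), ("B", "i"), ("B", "j"),
        ("C", "i"), ("C", "j"), ("D", "k"), ("D", "l"), ("E", "l"),
    ]
    return BipartiteGraph(edges)


@pytest.fixture
def toy_projection(toy_graph):
    return project_weighted(toy_graph, "u")


@pytest.fixture
def random_graph_factory():
    return random_bipartite
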