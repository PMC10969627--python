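import numpy as np
import pytest

from fullersim.cage import CageGraph, build_c60


@pytest.fixture(scope="session")
def c60():
    """Ideal C60-Ih cage at 1.44 Å edge length (geometry, graph)."""
    return build_c60(1.44)


@pytest.fixture(scope="session")
def c60_graph(c60):
    return c60[1]


@pytest.fixture(scope="session")
def c60_geometry(c60):
    return c60[0]


def polyhedron_graph(name: str) -> CageGraph:
    """Small 3-regular test polyhedra as abstract graphs."""
    import networkx as nx

    if name == "cube":
        g = nx.hypercube_graph(3)
    elif name == "dodecahedron":
        g = nx.dodecahedral_graph()
    elif name == "tetrahedron":
        g = nx.complete_graph(4)
    elif name == "prism3":
        g = nx.circular_ladder_graph(3)
    else:
        raise ValueError(name)
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    return CageGraph(n_atoms=g.number_of_nodes(), edges=list(g.edges()))
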