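import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_triangles():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


@pytest.fixture
def path4():
    return nx.path_graph(4)


@pytest.fixture
def k4():
    return nx.complete_graph(4)
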