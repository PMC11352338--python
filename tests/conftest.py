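import networkx as nx
import numpy as np
import pytest

from flysin.interaction import InteractionCriteria
from flysin.synthetic import ArenaSpec


def graph_from_matrix(W) -> nx.DiGraph:
    """Directed graph from a dense weight matrix; both weight attrs set."""
    W = np.asarray(W, dtype=float)
    g = nx.DiGraph()
    g.add_nodes_from(range(len(W)))
    for i in range(len(W)):
        for j in range(len(W)):
            if W[i, j] > 0:
                g.add_edge(i, j, count=float(W[i, j]), duration_s=float(W[i, j]))
    return g


@pytest.fixture
def criteria():
    return InteractionCriteria()


@pytest.fixture
def arena():
    return ArenaSpec(duration_s=60.0)
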