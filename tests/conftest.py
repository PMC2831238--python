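import networkx as nx
import numpy as np
import pytest

from bpfs import ExpressionMatrix, PathwayGraph, fig1_fixture


@pytest.fixture(scope="session")
def fig1():
    """The worked-example signalling subgraph and its identity mapping."""
    return fig1_fixture()


@pytest.fixture
def toy_data():
    """4 samples x 3 features, perfectly separable on feature 'a'."""
    values = np.array(
        [
            [-1.0, 0.3, 1.0],
            [-0.8, -0.2, 1.0],
            [0.9, 0.1, 1.0],
            [1.1, -0.4, 1.0],
        ]
    )
    return ExpressionMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        feature_ids=["a", "b", "c"],
        values=values,
        labels=np.array([-1, -1, 1, 1]),
    )


def random_graph(n_vertices: int, edge_prob: float, seed: int) -> PathwayGraph:
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n_vertices))
    for i in range(n_vertices):
        for j in range(i + 1, n_vertices):
            if rng.random() < edge_prob:
                g.add_edge(i, j)
    return PathwayGraph(g)


def bfs_oracle(graph: PathwayGraph, source):
    """Hand-rolled breadth-first search: vertex -> hop distance from source."""
    dist = {source: 0}
    frontier = [source]
    adj = {v: set(graph.graph.neighbors(v)) for v in graph.graph.nodes}
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist
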