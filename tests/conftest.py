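import itertools

import numpy as np
import pytest

from netpattern.graph_core import Graph

# ----------------------------------------------------------- shared oracles


def brute_triangles(g: Graph) -> dict:
    """Exhaustive triple enumeration: independent oracle for per-node
    triangle membership on small graphs."""
    counts = {v: 0 for v in g.node_list}
    for a, b, c in itertools.combinations(g.node_list, 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            counts[a] += 1
            counts[b] += 1
            counts[c] += 1
    return counts


def brute_clustering(g: Graph) -> dict:
    """Local clustering from the brute-force triangle counts."""
    deg = g.degrees()
    tri = brute_triangles(g)
    return {
        v: (2.0 * tri[v] / (deg[v] * (deg[v] - 1)) if deg[v] >= 2 else 0.0)
        for v in g.node_list
    }


def dense_pagerank(g: Graph, damping: float = 0.85, iters: int = 5000) -> dict:
    """Dense power-iteration PageRank, written independently of the sparse
    implementation (explicit dense transition matrix)."""
    n = g.n_nodes
    ids = g.node_list
    A = np.zeros((n, n))
    for u, v in g.edges():
        iu, iv = ids.index(u), ids.index(v)
        A[iu, iv] = A[iv, iu] = 1.0
    deg = A.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        if deg[i] > 0:
            P[i] = A[i] / deg[i]
        else:
            P[i] = 1.0 / n  # dangling: spread uniformly
    x = np.full(n, 1.0 / n)
    for _ in range(iters):
        x = (1.0 - damping) / n + damping * (P.T @ x)
    return dict(zip(ids, x))


def complete_graph(n: int) -> Graph:
    return Graph.from_edges(itertools.combinations(range(n), 2), nodes=range(n))


@pytest.fixture
def k4() -> Graph:
    return complete_graph(4)


@pytest.fixture(scope="session")
def pub_trajectory():
    """Yearly trajectory of the default synthetic publication stream,
    shared across tests (the stream build takes a few seconds)."""
    from netpattern.synthetic_data import SynthPubConfig, make_publications
    from netpattern.topic_net import cumulative_networks, yearly_trajectory

    records = make_publications(SynthPubConfig(seed=13))
    return yearly_trajectory(cumulative_networks(records))


@pytest.fixture
def desk_dataset():
    """Small separable image set shared by the trained-network tests."""
    from netpattern.synthetic_data import desk_image_profile, make_images

    return make_images(desk_image_profile(seed=11))
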