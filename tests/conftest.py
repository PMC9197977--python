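import itertools

import networkx as nx
import numpy as np
import pytest

from spreadrank import toy_network, synthetic_graph


@pytest.fixture(scope="session")
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def toy_graph(toy):
    return toy.network


@pytest.fixture(scope="session")
def random_graphs():
    """Twenty small connected BA/ER/WS graphs for oracle/property tests."""
    graphs = []
    for seed in range(7):
        graphs.append(synthetic_graph("ba", n=25, m=2, rng_seed=seed))
    for seed in range(7):
        g = synthetic_graph("er", n=25, p=0.18, rng_seed=seed)
        comps = sorted(nx.connected_components(g), key=len)
        graphs.append(g.subgraph(comps[-1]).copy())
    for seed in range(6):
        graphs.append(synthetic_graph("ws", n=25, k=4, p=0.2, rng_seed=seed))
    assert len(graphs) == 20
    return graphs


def floyd_warshall_distances(g):
    """Brute-force all-pairs hop distances, independent of BFS."""
    nodes = list(g)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges():
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k, i, j in itertools.product(range(n), repeat=3):
        if d[i, k] + d[k, j] < d[i, j]:
            d[i, j] = d[i, k] + d[k, j]
    return nodes, d
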