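"""Built-in fixtures and synthetic graph generators.

The 9-node toy network is the package's ground-truth anchor: its degree,
k-shell, eigenvector-centrality and multi-characteristics gravity scores
are known to four decimal places, so every stage of the pipeline can be
checked end to end without downloading anything.  The synthetic generators
wrap the classic random-graph models for property tests and scaled-down
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["ToyFixture", "toy_network", "synthetic_graph"]

# 13 edges of the toy network, hard-coded: this is the repo's anchor.
_TOY_EDGES = [
    ("1", "2"), ("2", "3"), ("2", "7"), ("3", "4"), ("3", "7"),
    ("4", "5"), ("4", "6"), ("4", "7"), ("5", "6"), ("5", "7"),
    ("5", "8"), ("6", "7"), ("6", "9"),
]

_TOY_DC = {"1": 1, "2": 3, "3": 3, "4": 4, "5": 4, "6": 4, "7": 5, "8": 1, "9": 1}
_TOY_KS = {"1": 1, "2": 2, "3": 2, "4": 3, "5": 3, "6": 3, "7": 3, "8": 1, "9": 1}
# 4-decimal printed eigenvector centralities (unit-sum normalization)
_TOY_EC = {
    "1": 0.0259, "2": 0.0943, "3": 0.1256, "4": 0.1714, "5": 0.1534,
    "6": 0.1534, "7": 0.1917, "8": 0.0421, "9": 0.0421,
}
# multi-characteristics gravity scores at truncation radius 2, α-normalized
_TOY_MCGM = {
    "1": 1.9679, "2": 13.1293, "3": 16.9320, "4": 29.0955, "5": 26.0652,
    "6": 26.0652, "7": 35.9099, "8": 3.4704, "9": 3.4704,
}
_TOY_ALPHA = 0.9827


@dataclass(frozen=True)
class ToyFixture:
    """The 9-node toy network with its published per-node expectations."""

    network: nx.Graph = field(repr=False)
    expected_dc: dict = field(default_factory=lambda: dict(_TOY_DC))
    expected_ks: dict = field(default_factory=lambda: dict(_TOY_KS))
    expected_ec: dict = field(default_factory=lambda: dict(_TOY_EC))
    expected_mcgm: dict = field(default_factory=lambda: dict(_TOY_MCGM))
    expected_alpha: float = _TOY_ALPHA


def toy_network() -> ToyFixture:
    """The 9-node, 13-edge toy fixture with all printed expectations attached."""
    g = nx.Graph()
    g.add_edges_from(_TOY_EDGES)
    return ToyFixture(network=g)


def synthetic_graph(kind: str, rng_seed: int | None = None, **params) -> nx.Graph:
    """Reproducible synthetic simple graphs for tests and experiments.

    Kinds: ``er`` (n, p), ``ba`` (n, m), ``ws`` (n, k, p), ``ring`` (n),
    ``star`` (n = number of leaves), ``path`` (n), ``regular`` (n, d).
    Node labels are strings; generation is deterministic given ``rng_seed``.
    """
    if kind == "er":
        g = nx.erdos_renyi_graph(params["n"], params["p"], seed=rng_seed)
    elif kind == "ba":
        g = nx.barabasi_albert_graph(params["n"], params["m"], seed=rng_seed)
    elif kind == "ws":
        n, k, p = params["n"], params["k"], params["p"]
        if k % 2:
            raise ValueError("small-world ring degree k must be even")
        g = nx.watts_strogatz_graph(n, k, p, seed=rng_seed)
    elif kind == "ring":
        g = nx.cycle_graph(params["n"])
    elif kind == "star":
        g = nx.star_graph(params["n"])
    elif kind == "path":
        g = nx.path_graph(params["n"])
    elif kind == "regular":
        g = nx.random_regular_graph(params["d"], params["n"], seed=rng_seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    return nx.relabel_nodes(g, {n: str(n) for n in g})
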