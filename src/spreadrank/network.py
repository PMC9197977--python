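"""Graph container, edge-list I/O, BFS distances and whole-graph topology statistics.

The package operates on undirected, unweighted simple graphs.  Graphs are
held as :class:`networkx.Graph` objects whose node labels are opaque strings;
every public function in the package accepts and returns such graphs, so the
full networkx toolbox remains available to callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyStats",
    "load_edgelist",
    "bfs_distances",
    "largest_connected_component",
    "topology_stats",
    "epidemic_threshold_from_moments",
]


@dataclass(frozen=True)
class TopologyStats:
    """Summary statistics of one undirected simple graph.

    Attributes
    ----------
    n_nodes, n_edges : int
        N and M.
    avg_degree : float
        ⟨k⟩ = 2M/N, first moment of the degree sequence.
    second_moment : float
        ⟨k²⟩, second moment of the degree sequence.
    avg_distance : float
        ⟨d⟩, mean shortest-path length over unordered distinct pairs.
    clustering : float
        Mean of local clustering coefficients (Watts–Strogatz convention;
        nodes of degree < 2 contribute 0).
    assortativity : float
        Degree Pearson correlation over edge endpoints.
    heterogeneity : float
        H = ⟨k²⟩/⟨k⟩² ≥ 1; equals 1 only for regular graphs.
    epidemic_threshold : float
        β_c ≈ ⟨k⟩/(⟨k²⟩ − ⟨k⟩), the heterogeneous-mean-field SIR threshold
        for recovery probability 1.
    """

    n_nodes: int
    n_edges: int
    avg_degree: float
    second_moment: float
    avg_distance: float
    clustering: float
    assortativity: float
    heterogeneity: float
    epidemic_threshold: float

    def to_dict(self) -> dict:
        return asdict(self)


def load_edgelist(path: str | Path, delimiter: str | None = None) -> nx.Graph:
    """Read an undirected simple graph from a plain-text edge list.

    One edge per line, two node labels; ``#``-prefixed lines are comments.
    The delimiter is auto-detected (comma vs. whitespace) unless given.
    Self-loops and duplicate edges are dropped with a logged count; node
    labels are preserved as strings.

    Raises
    ------
    ValueError
        On a malformed line (fewer than two tokens) or an empty file.
    """
    path = Path(path)
    g = nx.Graph()
    n_selfloops = 0
    n_duplicates = 0
    n_edge_lines = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is not None:
                tokens = [t for t in line.split(delimiter) if t.strip()]
            elif "," in line:
                tokens = [t for t in line.split(",") if t.strip()]
            else:
                tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two node labels, got {line!r}"
                )
            u, v = tokens[0].strip(), tokens[1].strip()
            n_edge_lines += 1
            if u == v:
                n_selfloops += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_duplicates += 1
                continue
            g.add_edge(u, v)
    if n_edge_lines == 0:
        raise ValueError(f"{path}: no edges found")
    if n_selfloops or n_duplicates:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path, n_selfloops, n_duplicates,
        )
    return g


def bfs_distances(g: nx.Graph, source) -> dict:
    """Hop distances from ``source`` to every reachable node (source included, 0).

    Unreachable nodes are absent from the returned mapping.
    """
    if source not in g:
        raise KeyError(f"source node {source!r} not in graph")
    return dict(nx.single_source_shortest_path_length(g, source))


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken toward the component
    containing the lexicographically smallest node label.  Logs when nodes
    are discarded.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no connected component")
    components = sorted(
        nx.connected_components(g),
        key=lambda c: (-len(c), min(str(n) for n in c)),
    )
    keep = components[0]
    if len(keep) < g.number_of_nodes():
        logger.info(
            "restricting to largest connected component: kept %d of %d nodes",
            len(keep), g.number_of_nodes(),
        )
    return g.subgraph(keep).copy()


def epidemic_threshold_from_moments(k_mean: float, k2_mean: float) -> float:
    """SIR epidemic threshold β_c ≈ ⟨k⟩/(⟨k²⟩ − ⟨k⟩) from degree moments."""
    if k2_mean <= k_mean:
        raise ValueError(
            f"second moment ({k2_mean}) must exceed mean degree ({k_mean})"
        )
    return k_mean / (k2_mean - k_mean)


def topology_stats(g: nx.Graph) -> TopologyStats:
    """Compute the topology summary row for one graph.

    If ``g`` is disconnected the average distance is computed on the largest
    connected component (with a warning); all other statistics use the full
    graph.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes for topology statistics")
    m = g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    k_mean = sum(degrees) / n
    k2_mean = sum(d * d for d in degrees) / n
    if nx.is_connected(g):
        d_mean = nx.average_shortest_path_length(g)
    else:
        logger.warning("graph disconnected; average distance computed on LCC")
        d_mean = nx.average_shortest_path_length(largest_connected_component(g))
    clustering = nx.average_clustering(g)  # mean of local C, deg<2 -> 0
    try:
        # regular graphs have zero degree variance; report nan quietly
        with np.errstate(invalid="ignore", divide="ignore"):
            assortativity = float(nx.degree_assortativity_coefficient(g))
    except (ValueError, ZeroDivisionError):
        assortativity = float("nan")
    heterogeneity = k2_mean / k_mean**2
    return TopologyStats(
        n_nodes=n,
        n_edges=m,
        avg_degree=k_mean,
        second_moment=k2_mean,
        avg_distance=d_mean,
        clustering=clustering,
        assortativity=assortativity,
        heterogeneity=heterogeneity,
        epidemic_threshold=epidemic_threshold_from_moments(k_mean, k2_mean),
    )
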