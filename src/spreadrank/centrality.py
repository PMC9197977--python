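"""The six classic benchmark centralities: DC, H-index, k-shell, EC, BC, CC.

Degree, H-index and k-shell are integer-valued local/semi-local indices;
eigenvector centrality is the leading-eigenvector score; betweenness and
closeness are the two path-based benchmarks.  All return a
:class:`~spreadrank.scores.ScoreTable` keyed by node label.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .scores import ScoreTable

__all__ = [
    "degree_centrality",
    "h_index",
    "k_shell",
    "eigenvector_centrality",
    "betweenness_centrality",
    "closeness_centrality",
]


def degree_centrality(g: nx.Graph) -> ScoreTable:
    """DC(i) = k(i), the number of neighbors."""
    return ScoreTable("dc", {n: int(d) for n, d in g.degree()})


def h_index(g: nx.Graph) -> ScoreTable:
    """H(i): the largest h such that at least h neighbors of i have degree ≥ h."""
    deg = dict(g.degree())
    scores = {}
    for i in g:
        nbr_degrees = sorted((deg[j] for j in g[i]), reverse=True)
        h = 0
        for rank, d in enumerate(nbr_degrees, start=1):
            if d >= rank:
                h = rank
            else:
                break
        scores[i] = h
    return ScoreTable("hindex", scores)


def k_shell(g: nx.Graph) -> ScoreTable:
    """Shell index by iterative pruning.

    Repeatedly remove every node of residual degree ≤ s (cascading) to form
    the s-shell, for s = 1, 2, …  Isolated nodes get shell 0: they are gone
    before the 1-shell forms.
    """
    residual = {n: d for n, d in g.degree()}
    scores = {}
    shell = 0
    while residual:
        # everything of residual degree <= shell peels off at this level
        to_remove = [n for n, d in residual.items() if d <= shell]
        if not to_remove:
            shell += 1
            continue
        while to_remove:
            batch, to_remove = to_remove, []
            for n in batch:
                scores[n] = shell
                del residual[n]
            for n in batch:
                for j in g[n]:
                    if j in residual:
                        residual[j] -= 1
                        if residual[j] <= shell and j not in to_remove:
                            to_remove.append(j)
            # dedupe while preserving determinism
            to_remove = list(dict.fromkeys(t for t in to_remove if t in residual))
    return ScoreTable("kshell", scores)


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-12, max_iter: int = 100_000
) -> ScoreTable:
    """Leading eigenvector of the adjacency matrix, normalized to unit sum.

    Deterministic power iteration from the uniform positive vector.  The
    returned scores x satisfy x = c·A·x with c the reciprocal of the largest
    eigenvalue, entrywise non-negative and summing to 1.

    Raises
    ------
    RuntimeError
        If the residual ‖x − c·A·x‖∞ has not dropped below ``tol`` after
        ``max_iter`` iterations.
    """
    nodes = list(g)
    a = nx.to_numpy_array(g, nodelist=nodes)
    x = np.full(len(nodes), 1.0 / len(nodes))
    residual = np.inf
    for _ in range(max_iter):
        ax = a @ x
        total = ax.sum()
        if total == 0:  # edgeless graph: uniform vector is as good as any
            break
        x_new = ax / total
        lam = (x @ ax) / (x @ x)
        residual = np.abs(x - ax / lam).max()
        x = x_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"power iteration did not converge: residual {residual:.3e} > tol {tol:.1e}"
        )
    return ScoreTable("ec", dict(zip(nodes, x.tolist())), {"tol": tol})


def betweenness_centrality(g: nx.Graph) -> ScoreTable:
    """Unnormalized shortest-path betweenness over unordered pairs s < t.

    BC(i) = Σ_{s≠i≠t} g_st(i)/g_st with g_st the number of shortest s–t
    paths; Brandes accumulation via networkx.
    """
    bc = nx.betweenness_centrality(g, normalized=False)
    return ScoreTable("bc", dict(bc))


def closeness_centrality(g: nx.Graph) -> ScoreTable:
    """CC(i) = (N−1) / Σ_{j≠i} d(i,j); requires a connected graph."""
    if g.number_of_nodes() > 1 and not nx.is_connected(g):
        raise ValueError(
            "closeness centrality requires a connected graph; "
            "restrict to the largest connected component first"
        )
    cc = nx.closeness_centrality(g)
    return ScoreTable("cc", dict(cc))
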