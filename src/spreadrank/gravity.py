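"""The gravity-model centrality family.

All members score node i by summing mass(i)·mass(j)/d(i,j)² over nodes j
within a truncation radius R, by analogy with Newtonian gravity; they differ
only in what plays the role of mass and in R:

========  ==========================  ====================  =====
method    focal mass                  neighbor mass         R
========  ==========================  ====================  =====
GC        k-shell                     k-shell               3
IGC       k-shell                     degree                3
LGM       degree                      degree                free
MCGM      normalized k + α·ks + EC    same                  free (default 2)
UGM       a·k + (1−a)·ks              b·k + (1−b)·ks        free
========  ==========================  ====================  =====

GC+ and IGC+ replace a node's score by the sum of the base score over its
1-hop neighbors.  The multi-characteristics model (MCGM) builds its mass
from the degree, k-shell and eigenvector-centrality values jointly, each
normalized by its maximum, with the k-shell term damped by the factor α
(see :func:`mcgm_alpha`) so that the narrow k-shell value space does not
dominate the sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .centrality import degree_centrality, eigenvector_centrality, k_shell
from .network import topology_stats
from .scores import ScoreTable

__all__ = [
    "AlphaStats",
    "neighborhood_within",
    "gravity_sum",
    "gc",
    "gc_plus",
    "lgm",
    "estimate_r_star",
    "mcgm_alpha",
    "mcgm",
    "ugm",
    "search_optimal_radius",
]

#: fixed truncation radius of the original gravity centrality (the ψ_i set)
GC_RADIUS = 3


@dataclass(frozen=True)
class AlphaStats:
    """Extrema and medians of degree, k-shell and EC, and the damping factor α.

    α = max{k_mid/k_max, x_mid/x_max} / (ks_mid/ks_max).  Because the
    k-shell index has a much narrower value space than degree or EC, its
    median/maximum ratio is larger; dividing by it pulls the k-shell term of
    the MCGM mass onto the same footing as the other two.
    """

    k_max: float
    ks_max: float
    x_max: float
    k_mid: float
    ks_mid: float
    x_mid: float
    alpha: float


def neighborhood_within(g: nx.Graph, i, radius: int) -> set:
    """All (j, d(i,j)) pairs with 1 ≤ d(i,j) ≤ radius, by truncated BFS."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    dist = nx.single_source_shortest_path_length(g, i, cutoff=radius)
    return {(j, d) for j, d in dist.items() if d >= 1}


def gravity_sum(
    g: nx.Graph, mass_focal: dict, mass_neighbor: dict, radius: int
) -> dict:
    """score(i) = Σ_{1≤d(i,j)≤radius} mass_focal(i)·mass_neighbor(j)/d(i,j)².

    Unreachable pairs (d = ∞) contribute nothing.  Raises KeyError when a
    node within range has no mass.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    scores = {}
    for i in g:
        total = 0.0
        for j, d in nx.single_source_shortest_path_length(g, i, cutoff=radius).items():
            if d >= 1:
                total += mass_focal[i] * mass_neighbor[j] / (d * d)
        scores[i] = total
    return scores


def gc(g: nx.Graph, variant: str = "gc") -> ScoreTable:
    """Gravity centrality (k-shell masses) or its improved form.

    ``variant="gc"``: both masses are the k-shell value; ``variant="igc"``:
    the focal node keeps its k-shell mass while neighbors contribute their
    degree.  The radius is fixed at 3 by definition.
    """
    if variant not in ("gc", "igc"):
        raise ValueError(f"unknown variant {variant!r}")
    ks = k_shell(g).scores
    neighbor_mass = dict(g.degree()) if variant == "igc" else ks
    return ScoreTable(
        variant, gravity_sum(g, ks, neighbor_mass, GC_RADIUS), {"radius": GC_RADIUS}
    )


def gc_plus(g: nx.Graph, variant: str = "gc+") -> ScoreTable:
    """Extended gravity centrality: sum of the base score over 1-hop neighbors.

    The focal node's own base score is excluded, exactly as the defining
    formula is written.
    """
    if variant not in ("gc+", "igc+"):
        raise ValueError(f"unknown variant {variant!r}")
    base = gc(g, variant[:-1]).scores
    scores = {i: sum(base[j] for j in g[i]) for i in g}
    return ScoreTable(variant, scores, {"radius": GC_RADIUS})


def lgm(g: nx.Graph, radius: int | str = "auto") -> ScoreTable:
    """Local gravity model: both masses are the degree, truncation radius R."""
    radius = _resolve_radius(g, radius)
    deg = dict(g.degree())
    return ScoreTable("lgm", gravity_sum(g, deg, deg, radius), {"radius": radius})


def estimate_r_star(avg_distance: float) -> int:
    """Estimated optimal truncation radius R* ≈ ⟨d⟩/2.

    Rounded half-up to an integer and floored at 1.
    """
    if avg_distance <= 0:
        raise ValueError("average distance must be positive")
    return max(1, int(np.floor(avg_distance / 2 + 0.5)))


def _resolve_radius(g: nx.Graph, radius: int | str) -> int:
    if radius == "auto":
        return estimate_r_star(topology_stats(g).avg_distance)
    radius = int(radius)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return radius


def mcgm_alpha(dc: ScoreTable, ks: ScoreTable, ec: ScoreTable) -> AlphaStats:
    """Compute the k-shell damping factor α from three score tables.

    The three tables must cover the same node set; medians use the standard
    convention (mean of the two middle order statistics for even counts).
    """
    if not (set(dc.scores) == set(ks.scores) == set(ec.scores)):
        raise ValueError("score tables cover different node sets")
    k = np.array(list(dc.scores.values()), dtype=float)
    s = np.array([ks.scores[n] for n in dc.scores], dtype=float)
    x = np.array([ec.scores[n] for n in dc.scores], dtype=float)
    k_max, ks_max, x_max = k.max(), s.max(), x.max()
    if min(k_max, ks_max, x_max) <= 0:
        raise ValueError("all maxima must be positive")
    k_mid, ks_mid, x_mid = np.median(k), np.median(s), np.median(x)
    if ks_mid <= 0:
        raise ValueError("median k-shell must be positive")
    alpha = max(k_mid / k_max, x_mid / x_max) / (ks_mid / ks_max)
    return AlphaStats(k_max, ks_max, x_max, k_mid, ks_mid, x_mid, float(alpha))


def mcgm(
    g: nx.Graph, radius: int | str = 2, normalization: str = "alpha"
) -> ScoreTable:
    """Multi-characteristics gravity model.

    The node mass combines degree, k-shell and eigenvector centrality:

    - ``normalization="none"``:  mass = k + k_s + x (raw sum);
    - ``normalization="plain"``: mass = k/k_max + k_s/ks_max + x/x_max;
    - ``normalization="alpha"`` (default): the plain form with the k-shell
      term multiplied by α, which damps the over-weighted k-shell index.

    The default truncation radius is 2, where the optimal radius of most
    real networks concentrates; ``radius="auto"`` estimates R* ≈ ⟨d⟩/2.
    """
    if normalization not in ("none", "plain", "alpha"):
        raise ValueError(f"unknown normalization {normalization!r}")
    radius = _resolve_radius(g, radius)
    dc_t, ks_t, ec_t = degree_centrality(g), k_shell(g), eigenvector_centrality(g)
    params: dict = {"radius": radius, "normalization": normalization}
    if normalization == "none":
        mass = {n: dc_t[n] + ks_t[n] + ec_t[n] for n in g}
    else:
        alpha = 1.0
        if normalization == "alpha":
            stats = mcgm_alpha(dc_t, ks_t, ec_t)
            alpha = stats.alpha
            params["alpha"] = alpha
        k_max = max(dc_t.scores.values())
        ks_max = max(ks_t.scores.values())
        x_max = max(ec_t.scores.values())
        mass = {
            n: dc_t[n] / k_max + alpha * ks_t[n] / ks_max + ec_t[n] / x_max
            for n in g
        }
    return ScoreTable("mcgm", gravity_sum(g, mass, mass, radius), params)


def ugm(g: nx.Graph, radius: int, a: float, b: float) -> ScoreTable:
    """Unified gravity model with mixing parameters a, b ∈ [0, 1].

    Focal mass a·k + (1−a)·k_s, neighbor mass b·k + (1−b)·k_s.  Degenerates
    to LGM at a=b=1, to GC at a=b=0 (R=3) and to IGC at a=0, b=1 (R=3).
    """
    deg = dict(g.degree())
    ks = k_shell(g).scores
    focal = {n: a * deg[n] + (1 - a) * ks[n] for n in g}
    neighbor = {n: b * deg[n] + (1 - b) * ks[n] for n in g}
    return ScoreTable(
        "ugm", gravity_sum(g, focal, neighbor, radius), {"radius": radius, "a": a, "b": b}
    )


def search_optimal_radius(g: nx.Graph, method, truth) -> tuple[int, float]:
    """Exhaustive truncation-radius search maximizing Kendall's τ against truth.

    ``method`` is a callable (g, radius) → ScoreTable; ``truth`` an
    InfluenceTable (or any object with a ``scores`` dict).  R runs from 1 to
    the graph diameter; ties break toward the smallest R.  Returns (R*, τ).
    """
    from .evaluation import kendall_tau  # local import to avoid a cycle

    nodes = list(g)
    truth_values = [truth.scores[n] for n in nodes]
    diameter = nx.diameter(g)
    best: tuple[int, float] | None = None
    for radius in range(1, max(diameter, 1) + 1):
        table = method(g, radius)
        tau = kendall_tau(table.aligned_values(nodes), truth_values).tau
        if best is None or tau > best[1]:
            best = (radius, tau)
    assert best is not None
    return best
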