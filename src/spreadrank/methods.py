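"""Name-keyed registry of all ranking methods, used by the CLI and the driver."""

from __future__ import annotations

import networkx as nx

from . import centrality, gravity
from .scores import ScoreTable

__all__ = ["METHOD_NAMES", "compute_method"]

_CLASSIC = {
    "dc": centrality.degree_centrality,
    "hindex": centrality.h_index,
    "kshell": centrality.k_shell,
    "ec": centrality.eigenvector_centrality,
    "bc": centrality.betweenness_centrality,
    "cc": centrality.closeness_centrality,
}

_GRAVITY = ("gc", "gc+", "igc", "igc+", "lgm", "mcgm", "ugm")

METHOD_NAMES = tuple(_CLASSIC) + _GRAVITY


def compute_method(
    name: str,
    g: nx.Graph,
    radius: int | str | None = None,
    a: float = 1.0,
    b: float = 1.0,
    normalization: str = "alpha",
) -> ScoreTable:
    """Run one ranking method by name.

    ``radius`` applies to lgm/mcgm/ugm only (gc/igc are fixed at 3 by
    definition); ``a``/``b`` to ugm; ``normalization`` to mcgm.
    """
    name = name.lower()
    if name in _CLASSIC:
        return _CLASSIC[name](g)
    if name in ("gc", "igc"):
        return gravity.gc(g, variant=name)
    if name in ("gc+", "igc+"):
        return gravity.gc_plus(g, variant=name)
    if name == "lgm":
        return gravity.lgm(g, radius if radius is not None else "auto")
    if name == "mcgm":
        return gravity.mcgm(
            g, radius if radius is not None else 2, normalization=normalization
        )
    if name == "ugm":
        if radius is None:
            raise ValueError("ugm requires an explicit radius")
        return gravity.ugm(g, int(radius), a, b)
    raise ValueError(f"unknown method {name!r}; choose from {METHOD_NAMES}")
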