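"""Rank-agreement statistics: tie-aware Kendall's τ and monotonicity.

The τ implemented here is the plain 2(n₊ − n₋)/(N(N−1)) form: a pair tied
in either sequence is neither concordant nor discordant but stays in the
denominator.  This is deliberately NOT the tau-b statistic (which
renormalizes the denominator for ties) — library tau-b must not be
substituted.

Monotonicity M(L) = [1 − Σ_r U_r(U_r−1) / (U(U−1))]² measures a ranking's
resolution: 1 when all scores are distinct, 0 when all are tied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scores import ScoreTable
from .sir import InfluenceTable

__all__ = ["RankComparison", "MonotonicityReport", "kendall_tau", "monotonicity", "evaluate_methods"]

_BLOCK = 512  # row block for the O(N²) pair count; bounds memory at N ~ 1e4


@dataclass(frozen=True)
class RankComparison:
    tau: float
    n_concordant: int
    n_discordant: int
    n_items: int


@dataclass(frozen=True)
class MonotonicityReport:
    m_value: float
    tie_groups: dict  # tied score -> group size, only groups of size >= 2


def kendall_tau(x, y) -> RankComparison:
    """Kendall's τ = 2(n₊ − n₋)/(N(N−1)) over all unordered index pairs.

    ``x`` and ``y`` are equal-length score sequences aligned by item.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 items")
    n_conc = 0
    n_disc = 0
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        # pairs (i, j) with i in the block, j > i
        sx = np.sign(x[start:stop, None] - x[None, :])
        sy = np.sign(y[start:stop, None] - y[None, :])
        upper = np.triu(np.ones((stop - start, n), dtype=bool), k=start + 1)
        prod = sx * sy
        n_conc += int(((prod > 0) & upper).sum())
        n_disc += int(((prod < 0) & upper).sum())
    tau = 2.0 * (n_conc - n_disc) / (n * (n - 1))
    return RankComparison(tau, n_conc, n_disc, n)


def monotonicity(scores: ScoreTable | dict, tie_precision: int = 9) -> MonotonicityReport:
    """Resolution of a ranking: penalizes tied scores, 1 = all distinct.

    Scores are grouped after rounding to ``tie_precision`` decimals so that
    float noise does not break genuine ties (e.g. structurally symmetric
    nodes must tie in every method).
    """
    values = scores.scores if isinstance(scores, ScoreTable) else scores
    u = len(values)
    if u < 2:
        raise ValueError("need at least 2 nodes")
    rounded = pd.Series([round(float(v), tie_precision) for v in values.values()])
    counts = rounded.value_counts()
    tie_sum = int((counts * (counts - 1)).sum())
    m = (1.0 - tie_sum / (u * (u - 1))) ** 2
    groups = {float(s): int(c) for s, c in counts.items() if c >= 2}
    return MonotonicityReport(m, groups)


def evaluate_methods(
    g, method_tables: list[ScoreTable], truth: InfluenceTable,
    tie_precision: int = 9,
) -> pd.DataFrame:
    """Tabulate τ against the SIR truth and monotonicity for each method.

    Returns one row per method with columns ``method``, ``tau``,
    ``monotonicity``, in the order given.  Scores are aligned to the truth
    by node label; a node-set mismatch raises with the offending labels.
    """
    nodes = list(truth.scores)
    truth_values = [truth.scores[n] for n in nodes]
    rows = []
    for table in method_tables:
        missing = set(nodes) ^ set(table.scores)
        if missing:
            raise ValueError(
                f"method {table.method!r}: node-set mismatch with truth: "
                f"{sorted(map(str, missing))[:10]}"
            )
        tau = kendall_tau(table.aligned_values(nodes), truth_values).tau
        mono = monotonicity(table, tie_precision).m_value
        rows.append({"method": table.method, "tau": tau, "monotonicity": mono})
    return pd.DataFrame(rows)
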