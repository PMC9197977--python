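"""The ScoreTable container shared by every centrality method."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ScoreTable"]


@dataclass
class ScoreTable:
    """One centrality's node → score mapping, tagged with method and parameters.

    Higher scores mean more influential.  Every node of the analyzed graph
    appears exactly once.
    """

    method: str
    scores: dict
    params: dict = field(default_factory=dict)

    def __getitem__(self, node) -> float:
        return self.scores[node]

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def aligned_values(self, node_order) -> list:
        """Scores in the given node order (KeyError on a missing node)."""
        return [self.scores[n] for n in node_order]

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready frame: node, score, rank (rank 1 = best, dense ties)."""
        s = pd.Series(self.scores, name="score")
        rank = s.rank(method="dense", ascending=False).astype(int)
        df = pd.DataFrame({"node": s.index, "score": s.values, "rank": rank.values})
        return df.sort_values(["rank", "node"], kind="stable").reset_index(drop=True)
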