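"""Borda-count aggregation of per-threshold-network gene rankings.

Each filtered network ranks its genes by boosted path score; position j
earns weight 1/j. A gene's voting score is the sum of its positional
weights across the networks that contain it, so stable high placement
across thresholds dominates a single lucky rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import GeneScoreTable

__all__ = ["ScoreMatrix", "rank_genes", "borda_weight", "voting_score"]


def rank_genes(scores: GeneScoreTable) -> dict[str, int]:
    """Competition-free positions 1..k by descending score.

    Ties break by ascending gene identifier; every gene gets a distinct
    position.
    """
    if not scores.scores:
        raise ValueError("cannot rank an empty score table")
    ordered = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return {g: i for i, (g, _) in enumerate(ordered, start=1)}


def borda_weight(position: int) -> float:
    """Positional weight 1/j: rank 1 -> 1, rank 2 -> 1/2, rank k -> 1/k."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return 1.0 / position


@dataclass
class ScoreMatrix:
    """Per-network score tables with their derived rank positions."""

    per_network: list[GeneScoreTable]
    positions: list[dict[str, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.positions = [rank_genes(t) for t in self.per_network]

    @property
    def k(self) -> list[int]:
        return [len(p) for p in self.positions]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.positions:
            out.update(p)
        return out


def voting_score(matrix: ScoreMatrix) -> dict[str, float]:
    """Sum of 1/position over the networks in which each gene appears.

    A gene filtered out of a network contributes nothing from it — absence
    across thresholds is penalized. Bounded by the number of networks,
    attained only by a gene ranked first everywhere.
    """
    votes: dict[str, float] = {g: 0.0 for g in matrix.all_genes()}
    for pos in matrix.positions:
        for g, j in pos.items():
            votes[g] += borda_weight(j)
    return votes
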