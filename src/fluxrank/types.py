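"""Shared domain types for the prioritization pipeline.

The interaction network itself is represented as a :class:`networkx.Graph`
over upper-cased gene symbols; the dataclasses here wrap the other pipeline
artifacts (expression data, seed sets, path lists, score tables, rankings)
and enforce their invariants at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"

__all__ = [
    "CONTROL",
    "CASE",
    "normalize_gene_id",
    "ExpressionDataset",
    "SeedSet",
    "PathList",
    "GeneScoreTable",
    "RankedEntry",
    "RankedGeneList",
    "EdgeFluxModel",
    "EdgeFluxRatio",
    "ThresholdSpec",
]


def normalize_gene_id(raw: str) -> str:
    """Canonical gene identifier: whitespace-trimmed, upper-cased symbol.

    Applied identically by every reader so that identifiers from the
    network, the expression matrix and gene lists always agree.
    """
    return raw.strip().upper()


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with a two-group sample partition.

    Values are taken as supplied (expression-summarized microarray scale,
    typically log-transformed); no preprocessing is applied.
    """

    values: pd.DataFrame  # genes (index) x samples (columns)
    group: pd.Series  # sample -> CONTROL | CASE

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier in expression matrix: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = set(self.values.columns) - set(self.group.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = set(self.group.unique()) - {CONTROL, CASE}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)} (expected control/case)")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError(
                f"need >= 2 samples per group for Pearson correlation, "
                f"got N={self.n_control} control, M={self.n_case} case"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_control(self) -> int:
        return int((self.group.loc[self.values.columns] == CONTROL).sum())

    @property
    def n_case(self) -> int:
        return int((self.group.loc[self.values.columns] == CASE).sum())

    def condition_samples(self, condition: str) -> list[str]:
        if condition not in (CONTROL, CASE):
            raise ValueError(f"unknown condition {condition!r}")
        mask = self.group.loc[self.values.columns] == condition
        return list(self.values.columns[mask.to_numpy()])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionDataset(self.values.loc[keep], self.group)


@dataclass(frozen=True)
class SeedSet:
    """Genes with prior validated disease association (the training set)."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("seed set is empty")

    def restrict_to(self, net: nx.Graph) -> "SeedSet":
        """Seeds present in the network; aborts if none survive."""
        present = frozenset(g for g in self.genes if net.has_node(g))
        if not present:
            raise ValueError("no seed gene present in the network; pipeline cannot proceed")
        return SeedSet(present)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass
class PathList:
    """Seed-containing shortest paths with their total edge-distance lengths."""

    paths: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for verts, _ in self.paths:
            out.update(verts)
        return out


@dataclass
class GeneScoreTable:
    """Per-gene scores for one threshold network.

    ``stage`` is ``"raw"`` (path scores in [0,1]) or ``"boosted"`` (after the
    (2 - clustering coefficient) structural factor, in [0,2]).
    """

    scores: dict[str, float]
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in ("raw", "boosted"):
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class RankedEntry:
    gene: str
    voting_score: float
    normalized_ade: float
    final_score: float
    rank: int


@dataclass
class RankedGeneList:
    """Final prioritization output: genes ordered by boosted voting score."""

    entries: list[RankedEntry]

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries, start=1):
            if e.rank != i:
                raise ValueError(f"ranks must be 1..n; entry {i} has rank {e.rank}")
            if e.final_score < e.voting_score - 1e-12:
                raise ValueError(f"final score below voting score for {e.gene}")

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def position(self, gene: str) -> int | None:
        for e in self.entries:
            if e.gene == gene:
                return e.rank
        return None


@dataclass
class EdgeFluxModel:
    """Random-walk state for one weighting condition.

    ``stochastic_matrix`` is row-stochastic on rows with at least one
    positively-weighted neighbor; ``edge_flux`` maps each ordered edge
    (i, j) to the stationary probability mass flowing i -> j.
    """

    node_order: list[str]
    stochastic_matrix: np.ndarray
    restart_vector: np.ndarray | None = None
    rwr_scores: np.ndarray | None = None
    restart_prob: float | None = None
    edge_flux: dict[tuple[str, str], float] | None = None

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.node_order)}


@dataclass
class EdgeFluxRatio:
    """log2 case/control edge-flux ratios on undirected edges."""

    values: dict[tuple[str, str], float]  # canonical (min,max) gene pair -> EF log-ratio
    reference: EdgeFluxModel | None = None


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-tail fractions of the EF distribution to retain (two-sided)."""

    tail_fractions: tuple[float, ...] = (0.025, 0.05, 0.10)

    def __post_init__(self) -> None:
        if not self.tail_fractions:
            raise ValueError("at least one tail fraction required")
        for t in self.tail_fractions:
            if not (0.0 < t < 0.5):
                raise ValueError(f"tail fraction {t} outside (0, 0.5)")
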