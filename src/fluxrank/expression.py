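"""Expression-derived quantities: condition-specific edge correlations, the
per-gene differential-expression value, its distance transform, and the
additive assignment of distances to network edges.

The differential-expression value of a gene is the absolute difference of
its control-group and case-group means. Mapped through a min-max
normalization and a negative natural log it becomes a *distance*: strongly
differential genes sit near 0, non-differential genes near -ln(floor). An
edge's distance is the sum of its two endpoints' transformed values, so
paths running through differential genes are short.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import networkx as nx
import numpy as np

from .types import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_EPSILON_FLOOR = 1e-6

__all__ = [
    "ConditionWeights",
    "compute_pcc_weights",
    "compute_expression_value",
    "transform_expression",
    "assign_edge_distances",
    "normalize_ade",
    "DEFAULT_EPSILON_FLOOR",
]


class ConditionWeights(dict):
    """Mapping canonical (min, max) gene pair -> Pearson correlation, for one condition."""

    def __init__(self, condition: str, weights: Mapping[tuple[str, str], float]):
        super().__init__(weights)
        self.condition = condition

    def __missing__(self, key: tuple[str, str]) -> float:
        # tolerate either orientation of the unordered pair
        rev = (key[1], key[0])
        if dict.__contains__(self, rev):
            return dict.__getitem__(self, rev)
        raise KeyError(key)


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def compute_pcc_weights(net: nx.Graph, expr: ExpressionDataset, condition: str) -> ConditionWeights:
    """Pearson correlation of each edge's endpoint genes over one condition's samples.

    Genes with zero variance within the condition yield weight 0 (with a
    logged warning) rather than an error, so network topology is preserved.
    """
    samples = expr.condition_samples(condition)
    mat = expr.values.loc[:, samples].to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(expr.values.index)}

    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))

    weights: dict[tuple[str, str], float] = {}
    n_degenerate = 0
    for u, v in net.edges():
        if u not in idx or v not in idx:
            missing = u if u not in idx else v
            raise KeyError(f"gene {missing!r} on a network edge is absent from the expression matrix")
        iu, iv = idx[u], idx[v]
        if norms[iu] == 0.0 or norms[iv] == 0.0:
            n_degenerate += 1
            weights[_canonical(u, v)] = 0.0
            continue
        r = float(np.dot(centered[iu], centered[iv]) / (norms[iu] * norms[iv]))
        weights[_canonical(u, v)] = max(-1.0, min(1.0, r))
    if n_degenerate:
        logger.warning(
            "%d edge(s) with a zero-variance gene in %s samples: correlation set to 0",
            n_degenerate,
            condition,
        )
    return ConditionWeights(condition, weights)


def compute_expression_value(expr: ExpressionDataset) -> dict[str, float]:
    """Per-gene absolute difference between control mean and case mean."""
    ctrl = expr.values.loc[:, expr.condition_samples("control")].mean(axis=1)
    case = expr.values.loc[:, expr.condition_samples("case")].mean(axis=1)
    return {g: float(abs(c - d)) for g, c, d in zip(expr.values.index, ctrl, case)}


def transform_expression(
    ev: Mapping[str, float], epsilon_floor: float = DEFAULT_EPSILON_FLOOR
) -> dict[str, float]:
    """Map differential-expression values onto non-negative distances.

    Each value is min-max normalized over the gene set and passed through
    -ln(.); the normalized value is clamped below at ``epsilon_floor`` so
    the gene at the minimum gets a large-but-finite distance (-ln(floor))
    instead of an undefined ln(0). The gene at the maximum maps to 0.
    """
    if not ev:
        raise ValueError("empty expression-value mapping")
    vals = np.asarray(list(ev.values()), dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("degenerate differential expression: all genes have identical values")
    out: dict[str, float] = {}
    for g, v in ev.items():
        z = (v - lo) / (hi - lo)
        z = min(1.0, max(epsilon_floor, z))
        out[g] = -math.log(z)
    return out


def assign_edge_distances(net: nx.Graph, tv: Mapping[str, float]) -> nx.Graph:
    """Weight each edge (u, v) with tv[u] + tv[v]; returns a new graph.

    The per-gene transformed values live on nodes, but shortest-path
    analysis needs edge distances, so the two endpoint values are added.
    """
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    for u, v in net.edges():
        for g in (u, v):
            if g not in tv:
                raise KeyError(f"no transformed expression value for gene {g!r}")
        w = tv[u] + tv[v]
        if w < 0:
            raise ValueError(f"negative edge distance {w} on ({u}, {v})")
        out.add_edge(u, v, weight=w)
    return out


def normalize_ade(ev: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalize average differential expression onto [0, 1].

    A constant vector (max == min) maps to all zeros: no differential
    signal means no boost.
    """
    if not ev:
        raise ValueError("empty expression-value mapping")
    vals = np.asarray(list(ev.values()), dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return {g: 0.0 for g in ev}
    return {g: (float(v) - lo) / (hi - lo) for g, v in ev.items()}
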