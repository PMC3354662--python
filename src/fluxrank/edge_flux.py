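"""Condition-specific network filtering by random-walk edge flux.

A row-stochastic transition matrix is built from |Pearson| edge weights,
a random walk with restart (restart probability gamma, restarting on the
seed genes by default) yields stationary node probabilities, and the flux
across each edge is the source node's stationary probability times the
transition probability. The log2 ratio of case flux over control flux is
the per-edge dysregulation statistic; edges in the two tails of its
distribution (normal fit, per-tail fraction t) define the filtered
subnetworks handed to the shortest-path stage.
"""

from __future__ import annotations

import logging
from typing import Mapping

import networkx as nx
import numpy as np

from .expression import ConditionWeights
from .types import EdgeFluxModel, EdgeFluxRatio, SeedSet, ThresholdSpec

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.3
DEFAULT_PSEUDO = 1e-12
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000

__all__ = [
    "build_stochastic_matrix",
    "make_restart_vector",
    "run_rwr",
    "compute_edge_flux",
    "undirected_flux",
    "run_edge_flux_model",
    "compute_ef_log_ratio",
    "threshold_ef_networks",
    "DEFAULT_GAMMA",
    "DEFAULT_PSEUDO",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
]


def build_stochastic_matrix(net: nx.Graph, w: ConditionWeights) -> EdgeFluxModel:
    """Row-normalize absolute edge weights into a transition matrix.

    Entry (i, j) is |w(i,j)| / sum_k |w(i,k)| over i's neighbors. Negative
    correlations enter by absolute value (anti-correlation is still strong
    coexpression evidence). A node whose incident |weights| sum to 0 gets
    an all-zero row; such dangling rows teleport to the restart vector
    during the walk so probability is conserved.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes())
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    S = np.zeros((n, n), dtype=float)
    for u, v in net.edges():
        key = (u, v) if u <= v else (v, u)
        a = abs(float(w[key]))
        S[idx[u], idx[v]] = a
        S[idx[v], idx[u]] = a
    row_sums = S.sum(axis=1)
    nonzero = row_sums > 0
    S[nonzero] /= row_sums[nonzero, None]
    n_dangling = int((~nonzero).sum())
    if n_dangling:
        logger.debug("%d node(s) with zero total |weight|: dangling rows teleport", n_dangling)
    return EdgeFluxModel(node_order=nodes, stochastic_matrix=S)


def make_restart_vector(
    model: EdgeFluxModel, seeds: SeedSet | None, mode: str = "seeds"
) -> np.ndarray:
    """Restart distribution: uniform over in-network seeds, or over all nodes."""
    n = len(model.node_order)
    if mode == "uniform" or seeds is None:
        return np.full(n, 1.0 / n)
    if mode != "seeds":
        raise ValueError(f"unknown restart mode {mode!r}")
    present = [g for g in seeds if g in model.index]
    if not present:
        raise ValueError("no seed gene present in the network for the restart vector")
    p = np.zeros(n)
    for g in present:
        p[model.index[g]] = 1.0 / len(present)
    return p


def run_rwr(
    model: EdgeFluxModel,
    restart: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Iterate r <- (1-gamma) S^T r + gamma p to its fixed point.

    Dangling rows (all-zero in S) redistribute their probability mass onto
    the restart vector each step, the standard teleportation convention.
    Raises on non-convergence; the final L1 residual of the defining
    equation is checked post hoc.
    """
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"gamma must be in (0,1), got {gamma}")
    p = np.asarray(restart, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("restart vector must be a probability distribution")
    S = model.stochastic_matrix
    dangling = S.sum(axis=1) < 1e-15
    r = p.copy()
    for _ in range(max_iter):
        leaked = r[dangling].sum()
        r_new = (1.0 - gamma) * (S.T @ r + leaked * p) + gamma * p
        delta = float(np.abs(r_new - r).sum())
        r = r_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"RWR did not converge in {max_iter} iterations (residual {delta:.3e})")
    leaked = r[dangling].sum()
    residual = float(np.abs((1.0 - gamma) * (S.T @ r + leaked * p) + gamma * p - r).sum())
    if residual > 1e-9:
        raise RuntimeError(f"RWR fixed-point residual too large: {residual:.3e}")
    model.restart_vector = p
    model.restart_prob = gamma
    model.rwr_scores = r
    return r


def compute_edge_flux(model: EdgeFluxModel) -> dict[tuple[str, str], float]:
    """Directed edge flux: stationary probability of i times P(i -> j)."""
    if model.rwr_scores is None:
        raise ValueError("run_rwr must be called before computing edge flux")
    S = model.stochastic_matrix
    r = model.rwr_scores
    flux: dict[tuple[str, str], float] = {}
    rows, cols = np.nonzero(S)
    for i, j in zip(rows, cols):
        flux[(model.node_order[i], model.node_order[j])] = float(r[i] * S[i, j])
    model.edge_flux = flux
    return flux


def undirected_flux(model: EdgeFluxModel) -> dict[tuple[str, str], float]:
    """Summarize each undirected edge as the sum of its two directed fluxes."""
    if model.edge_flux is None:
        compute_edge_flux(model)
    out: dict[tuple[str, str], float] = {}
    for (u, v), f in model.edge_flux.items():
        key = (u, v) if u <= v else (v, u)
        out[key] = out.get(key, 0.0) + f
    return out


def run_edge_flux_model(
    net: nx.Graph,
    w: ConditionWeights,
    seeds: SeedSet | None,
    gamma: float = DEFAULT_GAMMA,
    restart_mode: str = "seeds",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EdgeFluxModel:
    """Convenience: stochastic matrix + RWR + per-edge flux for one condition."""
    model = build_stochastic_matrix(net, w)
    p = make_restart_vector(model, seeds, mode=restart_mode)
    run_rwr(model, p, gamma=gamma, tol=tol, max_iter=max_iter)
    compute_edge_flux(model)
    return model


def compute_ef_log_ratio(
    case_flux: Mapping[tuple[str, str], float],
    control_flux: Mapping[tuple[str, str], float],
    pseudo: float = DEFAULT_PSEUDO,
    reference: EdgeFluxModel | None = None,
) -> EdgeFluxRatio:
    """log2((case + pseudo) / (control + pseudo)) per undirected edge.

    The pseudo-count keeps the ratio finite on edges with zero flux in one
    condition; the sign carries the direction of dysregulation.
    """
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")

    def canon(d: Mapping[tuple[str, str], float]) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for (u, v), f in d.items():
            key = (u, v) if u <= v else (v, u)
            out[key] = out.get(key, 0.0) + f
        return out

    ca = canon(case_flux)
    co = canon(control_flux)
    edges = {e for e, f in ca.items() if f != 0.0} | {e for e, f in co.items() if f != 0.0}
    values = {
        e: float(np.log2((ca.get(e, 0.0) + pseudo) / (co.get(e, 0.0) + pseudo))) for e in sorted(edges)
    }
    return EdgeFluxRatio(values=values, reference=reference)


def threshold_ef_networks(
    ratio: EdgeFluxRatio,
    net: nx.Graph,
    dist: Mapping[tuple[str, str], float] | nx.Graph,
    spec: ThresholdSpec,
) -> list[nx.Graph]:
    """Emit one subnetwork per tail fraction, keeping extreme-EF edges.

    The EF sample's mean and sample standard deviation define a normal
    reference; for per-tail fraction t an edge survives when its EF lies
    outside mean +/- z(1-t)*sd. Surviving edges are re-weighted with the
    differential-expression distances and isolated nodes are dropped.
    Smaller fractions give nested subsets of larger ones.
    """
    from scipy.stats import norm

    if not ratio.values:
        raise ValueError("empty edge-flux ratio sample")
    if isinstance(dist, nx.Graph):
        dist = {(min(u, v), max(u, v)): d["weight"] for u, v, d in dist.edges(data=True)}

    ef = np.asarray(list(ratio.values.values()), dtype=float)
    mu = float(ef.mean())
    sd = float(ef.std(ddof=1)) if len(ef) > 1 else 0.0

    nets: list[nx.Graph] = []
    for t in spec.tail_fractions:
        sub = nx.Graph()
        if sd > 0:
            cut = norm.ppf(1.0 - t) * sd
            for (u, v), e in ratio.values.items():
                if abs(e - mu) > cut and net.has_edge(u, v):
                    key = (u, v) if u <= v else (v, u)
                    if key not in dist:
                        raise KeyError(f"no distance for retained edge {key}")
                    sub.add_edge(u, v, weight=dist[key])
        if sub.number_of_edges() == 0:
            logger.warning("tail fraction %g retained no edges: emitting empty network", t)
        nets.append(sub)
    return nets
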