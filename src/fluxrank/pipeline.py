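"""End-to-end orchestration: network + expression + seeds -> ranked genes.

Stage order: universe intersection -> condition correlations -> edge-flux
filter (one subnetwork per tail threshold, re-weighted with differential-
expression distances) -> seed-path scoring with structural boost per
network -> Borda vote across networks -> expression boost -> ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import boost, edge_flux, expression, io, paths, voting
from .config import PipelineConfig
from .types import ExpressionDataset, RankedGeneList, SeedSet, ThresholdSpec

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "rank_from_objects", "evaluate", "StageMetrics"]


@dataclass
class StageMetrics:
    """Machine-readable per-stage summary, filled as the pipeline runs."""

    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, **kv) -> None:
        self.records.append({"stage": stage, **kv})
        logger.info("%s: %s", stage, ", ".join(f"{k}={v}" for k, v in kv.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def rank_from_objects(
    net: nx.Graph,
    expr: ExpressionDataset,
    seeds: SeedSet,
    cfg: PipelineConfig | None = None,
    metrics: StageMetrics | None = None,
    return_ef: bool = False,
):
    """Run the full method on in-memory objects; the library-level entry point."""
    cfg = cfg or PipelineConfig()
    metrics = metrics if metrics is not None else StageMetrics()

    net, expr = io.intersect_universe(net, expr)
    seeds = seeds.restrict_to(net)
    metrics.add(
        "universe",
        n_genes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        n_seeds=len(seeds),
    )

    w_control = expression.compute_pcc_weights(net, expr, "control")
    w_case = expression.compute_pcc_weights(net, expr, "case")

    ev = expression.compute_expression_value(expr)
    tv = expression.transform_expression(ev, epsilon_floor=cfg.epsilon_floor)
    dist_net = expression.assign_edge_distances(net, tv)
    nade = expression.normalize_ade(ev)
    metrics.add("expression", n_edges_weighted=dist_net.number_of_edges())

    ref = edge_flux.run_edge_flux_model(
        net, w_control, seeds, gamma=cfg.gamma, restart_mode=cfg.restart_mode,
        tol=cfg.tol, max_iter=cfg.max_iter,
    )
    case_model = edge_flux.run_edge_flux_model(
        net, w_case, seeds, gamma=cfg.gamma, restart_mode=cfg.restart_mode,
        tol=cfg.tol, max_iter=cfg.max_iter,
    )
    ratio = edge_flux.compute_ef_log_ratio(
        edge_flux.undirected_flux(case_model),
        edge_flux.undirected_flux(ref),
        pseudo=cfg.pseudo,
        reference=ref,
    )
    metrics.add("edge_flux", n_edges_with_flux=len(ratio.values))

    spec = ThresholdSpec(tuple(cfg.tail_fractions))
    subnets = edge_flux.threshold_ef_networks(ratio, dist_net, dist_net, spec)
    for t, sub in zip(spec.tail_fractions, subnets):
        metrics.add(
            "threshold_network",
            tail_fraction=t,
            n_nodes=sub.number_of_nodes(),
            n_edges=sub.number_of_edges(),
        )

    tables = []
    for t, sub in zip(spec.tail_fractions, subnets):
        table = paths.score_network(
            sub, seeds, cap_per_pair=cfg.cap_per_pair, length_floor=cfg.length_floor
        )
        if table is None:
            logger.warning("tail fraction %g: no seed-containing paths; network skipped", t)
            continue
        metrics.add("sp_scoring", tail_fraction=t, n_scored=len(table.scores))
        tables.append(table)
    if not tables:
        raise RuntimeError("no seed-connected structure in any threshold network")

    votes = voting.voting_score(voting.ScoreMatrix(tables))
    n_unvoted = 0
    for g in net.nodes():  # genes filtered out of every network stay ranked, at score 0
        if g not in votes:
            votes[g] = 0.0
            n_unvoted += 1
    metrics.add("voting", n_voted=len(votes) - n_unvoted, n_unvoted=n_unvoted, n_networks=len(tables))

    ranking = boost.final_score(votes, nade, exclude=seeds.genes if cfg.exclude_seeds else ())
    metrics.add("final", n_ranked=len(ranking))
    if return_ef:
        return ranking, ratio
    return ranking


def run_pipeline(cfg: PipelineConfig, metrics: StageMetrics | None = None) -> RankedGeneList:
    """File-level entry point driven by a :class:`PipelineConfig`."""
    for key in ("network_path", "expression_path", "groups_path", "seeds_path"):
        if getattr(cfg, key) is None:
            raise ValueError(f"config is missing {key}")
    net = io.read_network(cfg.network_path)
    expr = io.read_expression(cfg.expression_path, cfg.groups_path)
    seeds = io.read_gene_list(cfg.seeds_path)
    ranking = rank_from_objects(net, expr, seeds, cfg, metrics=metrics)
    if cfg.output_path:
        io.write_ranking(ranking, cfg.output_path)
    return ranking


def evaluate(
    ranking: RankedGeneList, targets: set[str], ks: list[int]
) -> pd.DataFrame:
    """Top-k benchmark table: count, precision, recall, average position.

    ``average_position`` is the mean rank of the targets found in the top
    k (NaN when none are found), the tie-breaking summary used alongside
    raw counts in prioritization benchmarks.
    """
    if not targets:
        raise ValueError("empty target set")
    found_pos = [e.rank for e in ranking.entries if e.gene in targets]
    rows = []
    for k in ks:
        in_top = [p for p in found_pos if p <= k]
        rows.append(
            {
                "k": k,
                "count": len(in_top),
                "precision": len(in_top) / k,
                "recall": len(in_top) / len(targets),
                "average_position": float(np.mean(in_top)) if in_top else float("nan"),
            }
        )
    return pd.DataFrame(rows)
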