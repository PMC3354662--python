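"""Readers and writers for edge lists, expression matrices, gene lists and rankings.

All files are UTF-8, tab-delimited. Gene identifiers pass through
:func:`fluxrank.types.normalize_gene_id` in every reader.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .types import (
    CASE,
    CONTROL,
    ExpressionDataset,
    RankedEntry,
    RankedGeneList,
    SeedSet,
    normalize_gene_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "read_expression",
    "read_gene_list",
    "packaged_seed_path",
    "write_ranking",
    "read_ranking",
    "write_network",
    "intersect_universe",
]


def read_network(path: str | Path, weighted: bool = False, sif: bool = False) -> nx.Graph:
    """Parse a headerless TSV edge list into an undirected network.

    Lines are ``gene_a<TAB>gene_b[<TAB>weight]``; with ``sif=True`` the
    middle column of a three-column SIF line is the interaction type and is
    ignored. Self-loops are dropped (logged), duplicate edges collapse to
    one, and symbols are upper-cased.
    """
    path = Path(path)
    net = nx.Graph()
    n_self = 0
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            n_lines += 1
            parts = [p for p in line.split("\t") if p.strip()]
            if len(parts) == 1:  # fall back to whitespace splitting
                parts = line.split()
            if sif:
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF line needs 3 columns, got {len(parts)}")
                parts = [parts[0], parts[2]]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {len(parts)}")
            u = normalize_gene_id(parts[0])
            v = normalize_gene_id(parts[1])
            if u == v:
                n_self += 1
                net.add_node(u)
                continue
            if weighted:
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: weighted edge list needs 3 columns")
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                net.add_edge(u, v, weight=w)
            else:
                net.add_edge(u, v)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_self:
        logger.info("dropped %d self-loop(s) while reading %s", n_self, path)
    return net


def write_network(net: nx.Graph, path: str | Path, weighted: bool = False) -> None:
    """Serialize a network as a headerless TSV edge list (sorted, canonical pair order)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            if weighted:
                fh.write(f"{u}\t{v}\t{net[u][v]['weight']:.12g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_expression(
    path: str | Path,
    group_spec: Mapping[str, str] | str | Path,
) -> ExpressionDataset:
    """Read a gene x sample TSV (first column = gene) with a control/case assignment.

    ``group_spec`` is either a mapping ``sample -> 'control'|'case'`` or the
    path of a two-column TSV sidecar with those assignments.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    df.index = [normalize_gene_id(str(g)) for g in df.index]
    dup = pd.Index(df.index)[pd.Index(df.index).duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene row {dup[0]!r}")

    if isinstance(group_spec, (str, Path)):
        side = pd.read_csv(group_spec, sep="\t", header=None, names=["sample", "group"], comment="#")
        mapping = {str(r["sample"]).strip(): str(r["group"]).strip().lower() for _, r in side.iterrows()}
    else:
        mapping = {str(k): str(v).strip().lower() for k, v in group_spec.items()}

    missing = [s for s in df.columns if s not in mapping]
    if missing:
        raise ValueError(f"{path}: sample(s) without group label: {missing}")
    group = pd.Series({s: mapping[s] for s in df.columns})
    return ExpressionDataset(values=df.astype(float), group=group)


def read_gene_list(path: str | Path) -> SeedSet:
    """Read a plain-text gene list (one symbol per line, ``#`` comments)."""
    path = Path(path)
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(normalize_gene_id(line))
    if not genes:
        raise ValueError(f"{path}: no genes after parsing")
    return SeedSet(frozenset(genes))


def packaged_seed_path() -> Path:
    """Path of the packaged prostate-cancer seed list (15 OMIM genes)."""
    return Path(str(resources.files("fluxrank.data") / "prostate_seeds.txt"))


_RANK_COLUMNS = ["rank", "gene", "voting_score", "normalized_ade", "final_score"]


def write_ranking(r: RankedGeneList, path: str | Path) -> None:
    """Write a ranking as TSV; values round-trip at 12 significant digits."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RANK_COLUMNS) + "\n")
        for e in r.entries:
            fh.write(
                f"{e.rank}\t{e.gene}\t{e.voting_score:.12g}\t"
                f"{e.normalized_ade:.12g}\t{e.final_score:.12g}\n"
            )


def read_ranking(path: str | Path) -> RankedGeneList:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _RANK_COLUMNS:
        raise ValueError(f"{path}: unexpected ranking header {list(df.columns)}")
    entries = [
        RankedEntry(
            gene=str(row.gene),
            voting_score=float(row.voting_score),
            normalized_ade=float(row.normalized_ade),
            final_score=float(row.final_score),
            rank=int(row.rank),
        )
        for row in df.itertuples()
    ]
    return RankedGeneList(entries)


def intersect_universe(net: nx.Graph, expr: ExpressionDataset) -> tuple[nx.Graph, ExpressionDataset]:
    """Restrict the analysis to genes present in both the network and the matrix.

    Mirrors the standard practice of intersecting the interaction network
    with the array platform before any scoring; drop counts are logged.
    """
    common = set(net.nodes()) & set(expr.genes)
    dropped_net = net.number_of_nodes() - len(common)
    dropped_expr = len(expr.genes) - len(common)
    if dropped_net or dropped_expr:
        logger.info(
            "universe intersection: dropped %d network gene(s), %d expression gene(s); %d remain",
            dropped_net,
            dropped_expr,
            len(common),
        )
    sub = net.subgraph(common).copy()
    return sub, expr.subset_genes(sorted(common))
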