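"""Desk-scale synthetic fixtures: a sparse interaction network with a
planted disease module and matched two-group expression matrices.

The background graph is preferential-attachment (scale-free degree
distribution, connected). A module of ``module_size`` genes containing the
seeds is densified with extra within-module edges, emulating the heavy
mutual interaction of disease genes. Control expression is per-gene
baseline plus Gaussian noise; case samples additionally shift module genes
by ``effect_size`` and share a latent factor (scaled by ``corr_strength``)
that induces within-module coexpression specific to the case condition —
exactly the contrast the edge-flux filter exploits. All randomness flows
from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .types import CASE, CONTROL, ExpressionDataset, SeedSet

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Generator parameters; defaults are the package's reference study conditions."""

    n_genes: int = 200
    attachment: int = 2  # preferential-attachment edges per new node
    n_seeds: int = 5
    module_size: int = 15
    n_control: int = 41
    n_case: int = 62
    effect_size: float = 2.5  # case-group mean shift on module genes (log2 units)
    corr_strength: float = 0.8  # latent-factor loading inducing case coexpression
    noise_sd: float = 1.0
    module_edge_prob: float = 0.35  # extra within-module edge probability
    baseline_mean: float = 8.0  # typical log2 microarray intensity
    baseline_sd: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size < self.n_seeds:
            raise ValueError("module_size must be >= n_seeds")
        if self.module_size > self.n_genes:
            raise ValueError("module larger than the gene universe")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need >= 2 samples per group")
        if not (0.0 <= self.corr_strength < 1.0):
            raise ValueError("corr_strength must be in [0, 1)")
        if self.attachment < 1 or self.attachment >= self.n_genes:
            raise ValueError("invalid attachment parameter")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[nx.Graph, ExpressionDataset, SeedSet, set[str]]:
    """Build (network, expression, seeds, truth) reproducibly from ``rng_seed``.

    ``truth`` is the full planted module (seeds included); pipeline
    evaluation typically scores recovery of the non-seed module genes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = _gene_names(spec.n_genes)

    # connected scale-free background
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g0 = nx.barabasi_albert_graph(spec.n_genes, spec.attachment, seed=ba_seed)
    net = nx.relabel_nodes(g0, {i: genes[i] for i in range(spec.n_genes)})

    # plant the module on a random gene subset; densify it
    module = sorted(rng.choice(spec.n_genes, size=spec.module_size, replace=False))
    module_genes = [genes[i] for i in module]
    for a in range(spec.module_size):
        for b in range(a + 1, spec.module_size):
            u, v = module_genes[a], module_genes[b]
            if not net.has_edge(u, v) and rng.random() < spec.module_edge_prob:
                net.add_edge(u, v)
    seeds = SeedSet(frozenset(module_genes[: spec.n_seeds]))

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    n_s = spec.n_control + spec.n_case
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_s))

    # case-only perturbation of module genes: mean shift + shared latent factor
    case_cols = np.arange(spec.n_control, n_s)
    factor = rng.normal(0.0, 1.0, size=spec.n_case)
    midx = np.asarray(module)
    loadings = np.where(rng.random(spec.module_size) < 0.5, 1.0, -1.0)  # mixed-sign coexpression
    values[np.ix_(midx, case_cols)] += spec.effect_size * loadings[:, None]
    values[np.ix_(midx, case_cols)] += (
        spec.corr_strength * 2.0 * loadings[:, None] * factor[None, :]
    )

    samples = [f"CTRL{i+1:03d}" for i in range(spec.n_control)] + [
        f"CASE{i+1:03d}" for i in range(spec.n_case)
    ]
    df = pd.DataFrame(values, index=genes, columns=samples)
    group = pd.Series(
        {s: (CONTROL if s.startswith("CTRL") else CASE) for s in samples}
    )
    expr = ExpressionDataset(values=df, group=group)
    return net, expr, seeds, set(module_genes)
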