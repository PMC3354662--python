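import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fluxrank.types import CASE, CONTROL, ExpressionDataset, SeedSet


def make_random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> nx.Graph:
    """Connected Erdos-Renyi-style graph with positive random edge weights."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            break
    out = nx.Graph()
    out.add_nodes_from(f"N{i:02d}" for i in range(n))
    for u, v in g.edges():
        out.add_edge(f"N{u:02d}", f"N{v:02d}", weight=float(rng.uniform(0.1, 5.0)))
    return out


def make_expression(
    genes: list[str], n_control: int = 4, n_case: int = 4, rng: np.random.Generator | None = None
) -> ExpressionDataset:
    rng = rng or np.random.default_rng(0)
    samples = [f"C{i}" for i in range(n_control)] + [f"D{i}" for i in range(n_case)]
    values = pd.DataFrame(
        rng.normal(8.0, 2.0, size=(len(genes), len(samples))), index=genes, columns=samples
    )
    group = pd.Series({s: (CONTROL if s.startswith("C") else CASE) for s in samples})
    return ExpressionDataset(values=values, group=group)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    """Unit-weight triangle A-B-C."""
    g = nx.Graph()
    for u, v in (("A", "B"), ("B", "C"), ("A", "C")):
        g.add_edge(u, v, weight=1.0)
    return g


@pytest.fixture
def seed_b():
    return SeedSet(frozenset({"B"}))
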