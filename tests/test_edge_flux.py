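"""Stochastic matrix, random walk with restart, edge flux and tail thresholds."""

import networkx as nx
import numpy as np
import pytest
from scipy.stats import norm

from fluxrank import edge_flux as efx
from fluxrank.expression import ConditionWeights
from fluxrank.types import EdgeFluxRatio, SeedSet, ThresholdSpec

from conftest import make_random_weighted_graph


def unit_weights(net):
    return ConditionWeights("control", {tuple(sorted(e)): 1.0 for e in net.edges()})


def graph_weights(net):
    return ConditionWeights("control", {tuple(sorted((u, v))): d["weight"] for u, v, d in net.edges(data=True)})


class TestStochasticMatrix:
    def test_path_graph_middle_row(self):
        g = nx.path_graph(["A", "B", "C"])
        m = efx.build_stochastic_matrix(g, unit_weights(g))
        i = m.index
        row = m.stochastic_matrix[i["B"]]
        assert row[i["A"]] == pytest.approx(0.5) and row[i["C"]] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, rng):
        g = make_random_weighted_graph(rng, 9)
        m = efx.build_stochastic_matrix(g, graph_weights(g))
        sums = m.stochastic_matrix.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_matches_hand_normalization(self, rng):
        g = make_random_weighted_graph(rng, 6)
        w = graph_weights(g)
        m = efx.build_stochastic_matrix(g, w)
        i = m.index
        for u in g.nodes():
            total = sum(abs(w[tuple(sorted((u, k)))]) for k in g.neighbors(u))
            for v in g.nodes():
                expected = abs(w[tuple(sorted((u, v)))]) / total if g.has_edge(u, v) else 0.0
                assert m.stochastic_matrix[i[u], i[v]] == pytest.approx(expected, abs=1e-12)

    def test_negative_weights_enter_by_absolute_value(self):
        g = nx.path_graph(["A", "B", "C"])
        w = ConditionWeights("control", {("A", "B"): -0.8, ("B", "C"): 0.2})
        m = efx.build_stochastic_matrix(g, w)
        i = m.index
        assert m.stochastic_matrix[i["B"], i["A"]] == pytest.approx(0.8)

    def test_all_zero_weights_dangling(self):
        g = nx.path_graph(["A", "B"])
        w = ConditionWeights("control", {("A", "B"): 0.0})
        m = efx.build_stochastic_matrix(g, w)
        assert m.stochastic_matrix.sum() == 0.0


class TestRwr:
    def test_two_node_symmetry(self):
        g = nx.path_graph(["A", "B"])
        m = efx.build_stochastic_matrix(g, unit_weights(g))
        for gamma in (0.1, 0.3, 0.7):
            r = efx.run_rwr(m, np.array([0.5, 0.5]), gamma=gamma)
            assert np.allclose(r, [0.5, 0.5], atol=1e-9)

    def test_high_gamma_approaches_restart(self, rng):
        g = make_random_weighted_graph(rng, 6)
        m = efx.build_stochastic_matrix(g, graph_weights(g))
        p = np.zeros(6)
        p[0] = 1.0
        r = efx.run_rwr(m, p, gamma=1 - 1e-9)
        assert np.allclose(r, p, atol=1e-6)

    def test_matches_linear_solve(self, rng):
        """Fixed point of the iteration equals gamma (I - (1-gamma) S^T)^-1 p."""
        g = make_random_weighted_graph(rng, 5)
        m = efx.build_stochastic_matrix(g, graph_weights(g))
        n = len(m.node_order)
        p = np.full(n, 1.0 / n)
        r = efx.run_rwr(m, p, gamma=0.3)
        S = m.stochastic_matrix
        closed = 0.3 * np.linalg.solve(np.eye(n) - 0.7 * S.T, p)
        assert np.allclose(r, closed, atol=1e-8)

    def test_scores_form_distribution(self, rng):
        g = make_random_weighted_graph(rng, 12)
        m = efx.build_stochastic_matrix(g, graph_weights(g))
        r = efx.run_rwr(m, np.full(12, 1 / 12), gamma=0.3)
        assert r.min() >= 0 and abs(r.sum() - 1.0) < 1e-9

    def test_dangling_teleport_conserves_probability(self):
        # isolated node C: its row is all-zero and must teleport
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("C")
        w = ConditionWeights("control", {("A", "B"): 1.0})
        m = efx.build_stochastic_matrix(g, w)
        r = efx.run_rwr(m, np.full(3, 1 / 3), gamma=0.3)
        assert abs(r.sum() - 1.0) < 1e-9

    def test_invalid_restart_rejected(self):
        g = nx.path_graph(["A", "B"])
        m = efx.build_stochastic_matrix(g, unit_weights(g))
        with pytest.raises(ValueError, match="probability"):
            efx.run_rwr(m, np.array([0.7, 0.7]))

    def test_seed_restart_vector(self):
        g = nx.path_graph(["A", "B", "C"])
        m = efx.build_stochastic_matrix(g, unit_weights(g))
        p = efx.make_restart_vector(m, SeedSet(frozenset({"A", "C", "ZZZ"})), mode="seeds")
        assert p[m.index["A"]] == 0.5 and p[m.index["C"]] == 0.5 and p[m.index["B"]] == 0.0


class TestEdgeFlux:
    def test_two_node_fluxes(self):
        g = nx.path_graph(["A", "B"])
        m = efx.build_stochastic_matrix(g, unit_weights(g))
        efx.run_rwr(m, np.array([0.5, 0.5]), gamma=0.3)
        flux = efx.compute_edge_flux(m)
        assert flux[("A", "B")] == pytest.approx(0.5)
        assert flux[("B", "A")] == pytest.approx(0.5)
        assert efx.undirected_flux(m)[("A", "B")] == pytest.approx(1.0)

    def test_total_flux_conserved(self, rng):
        g = make_random_weighted_graph(rng, 10)
        m = efx.build_stochastic_matrix(g, graph_weights(g))
        efx.run_rwr(m, np.full(10, 0.1), gamma=0.3)
        flux = efx.compute_edge_flux(m)
        assert sum(flux.values()) == pytest.approx(1.0, abs=1e-9)

    def test_elementwise_product_oracle(self, rng):
        g = make_random_weighted_graph(rng, 6)
        m = efx.build_stochastic_matrix(g, graph_weights(g))
        efx.run_rwr(m, np.full(6, 1 / 6), gamma=0.3)
        flux = efx.compute_edge_flux(m)
        i = m.index
        for (u, v), f in flux.items():
            assert f == pytest.approx(m.rwr_scores[i[u]] * m.stochastic_matrix[i[u], i[v]], abs=1e-15)
            assert f >= 0


class TestLogRatio:
    def test_equal_fluxes_zero(self):
        r = efx.compute_ef_log_ratio({("A", "B"): 0.3}, {("A", "B"): 0.3})
        assert r.values[("A", "B")] == pytest.approx(0.0)

    def test_doubling_gives_one(self):
        r = efx.compute_ef_log_ratio({("A", "B"): 2.0}, {("A", "B"): 1.0})
        assert r.values[("A", "B")] == pytest.approx(1.0, abs=1e-9)

    def test_random_pairs_match_formula(self, rng):
        case = {(f"G{i}", f"H{i}"): float(v) for i, v in enumerate(rng.uniform(0, 1, 20))}
        ctrl = {k: float(v) for k, v in zip(case, rng.uniform(0, 1, 20))}
        r = efx.compute_ef_log_ratio(case, ctrl, pseudo=1e-12)
        for k in case:
            expected = np.log2((case[k] + 1e-12) / (ctrl[k] + 1e-12))
            assert r.values[k] == pytest.approx(expected, abs=1e-12)

    def test_zero_control_flux_finite(self):
        r = efx.compute_ef_log_ratio({("A", "B"): 0.5}, {}, pseudo=1e-12)
        assert np.isfinite(r.values[("A", "B")])


class TestThresholds:
    def make_ratio(self, efs):
        return EdgeFluxRatio(values={(f"A{i:03d}", f"B{i:03d}"): float(e) for i, e in enumerate(efs)})

    def make_net_and_dist(self, ratio):
        net = nx.Graph()
        dist = {}
        for u, v in ratio.values:
            net.add_edge(u, v)
            dist[(u, v)] = 1.0
        return net, dist

    def test_constant_ef_all_empty(self):
        ratio = self.make_ratio([0.7] * 10)
        net, dist = self.make_net_and_dist(ratio)
        nets = efx.threshold_ef_networks(ratio, net, dist, ThresholdSpec((0.025, 0.05, 0.10)))
        assert all(n.number_of_edges() == 0 for n in nets)

    def test_near_half_fraction_keeps_most(self, rng):
        ratio = self.make_ratio(rng.normal(size=200))
        net, dist = self.make_net_and_dist(ratio)
        (sub,) = efx.threshold_ef_networks(ratio, net, dist, ThresholdSpec((0.499,)))
        assert sub.number_of_edges() > 190

    def test_matches_bruteforce_z_filter(self, rng):
        efs = rng.normal(size=100)
        ratio = self.make_ratio(efs)
        net, dist = self.make_net_and_dist(ratio)
        (sub,) = efx.threshold_ef_networks(ratio, net, dist, ThresholdSpec((0.05,)))
        mu, sd = efs.mean(), efs.std(ddof=1)
        expected = int(np.sum(np.abs(efs - mu) > norm.ppf(0.95) * sd))
        assert sub.number_of_edges() == expected

    def test_nesting(self, rng):
        ratio = self.make_ratio(rng.normal(size=150))
        net, dist = self.make_net_and_dist(ratio)
        nets = efx.threshold_ef_networks(ratio, net, dist, ThresholdSpec((0.025, 0.05, 0.10)))
        e = [set(map(frozenset, n.edges())) for n in nets]
        assert e[0] <= e[1] <= e[2]

    def test_retained_edges_reweighted_with_distances(self, rng):
        efs = list(rng.normal(size=50))
        ratio = self.make_ratio(efs)
        net, dist = self.make_net_and_dist(ratio)
        dist = {k: float(i) + 0.5 for i, k in enumerate(sorted(dist))}
        (sub,) = efx.threshold_ef_networks(ratio, net, dist, ThresholdSpec((0.10,)))
        for u, v, d in sub.edges(data=True):
            assert d["weight"] == dist[tuple(sorted((u, v)))]

    def test_deterministic(self, rng):
        efs = rng.normal(size=80)
        ratio = self.make_ratio(efs)
        net, dist = self.make_net_and_dist(ratio)
        spec = ThresholdSpec((0.05,))
        a = efx.threshold_ef_networks(ratio, net, dist, spec)[0]
        b = efx.threshold_ef_networks(ratio, net, dist, spec)[0]
        assert set(a.edges()) == set(b.edges())
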