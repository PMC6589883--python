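"""Spearman edge inference, keystone filtering, topology and MCODE."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilmfc import network as net
from soilmfc import simulate
from soilmfc.community import AbundanceTable
from oracles import graph_to_masks, mcode_modules_oracle, spearman_p_montecarlo


def small_table(data, sample_names=None):
    arr = np.asarray(data, dtype=float)
    if arr.min() < 0:  # abundance tables are non-negative; shift preserves ranks
        arr = arr - arr.min()
    counts = pd.DataFrame(arr)
    counts.columns = sample_names or [f"s{i}" for i in range(counts.shape[1])]
    taxa = pd.DataFrame({"kingdom": "bacteria", "lineage": ";;;;x"},
                        index=counts.index)
    samples = pd.DataFrame({"treatment": "t", "layer": "C"},
                           index=counts.columns)
    return AbundanceTable(counts, taxa, samples)


class TestSpearmanMatrix:
    def test_perfectly_monotone_pair(self):
        table = small_table([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12],
                             [2, 4, 8, 16, 20, 30, 40, 50, 60, 70, 80, 90]])
        rho, p = net.spearman_matrix(table)
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        assert p.iloc[0, 1] < 1e-6

    def test_diagonal_is_unity(self):
        rng = np.random.default_rng(1)
        table = small_table(rng.normal(size=(5, 12)))
        rho, _ = net.spearman_matrix(table)
        np.testing.assert_allclose(np.diag(rho.values), 1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            net.spearman_matrix(small_table([[1, 2, 3], [3, 2, 1]]))

    def test_zero_variance_feature_dropped(self):
        data = [[1, 2, 3, 4, 5], [5, 5, 5, 5, 5], [2, 1, 4, 3, 5]]
        with pytest.warns(UserWarning, match="zero-variance"):
            rho, _ = net.spearman_matrix(small_table(data))
        assert rho.shape == (2, 2)

    def test_exact_p_close_to_t_approximation_at_n9(self, rng):
        # at n=9 the exact permutation p and the t approximation agree
        # within Monte-Carlo error of an independent permutation sampler
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        table = small_table(np.vstack([x, y]))
        _, p_exact = net.spearman_matrix(table)
        p_mc = spearman_p_montecarlo(x, y, 4000, rng)
        se = np.sqrt(p_mc * (1 - p_mc) / 4000)
        assert abs(p_exact.iloc[0, 1] - p_mc) < 4 * se + 1e-3
        p_t = stats.spearmanr(x, y).pvalue
        assert abs(p_exact.iloc[0, 1] - p_t) < 0.05


class TestBuildNetwork:
    def test_all_insignificant_gives_empty_edges(self):
        rho = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        p = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        g = net.build_network(rho, p)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 3

    def test_edge_count_bound_and_signs(self, rng):
        table = small_table(rng.normal(size=(8, 20)))
        g = net.co_occurrence_network(table, alpha=0.5)
        n = g.number_of_nodes()
        assert g.number_of_edges() <= n * (n - 1) / 2
        for _, _, d in g.edges(data=True):
            assert d["sign"] == ("positive" if d["rho"] >= 0 else "negative")
            assert 0 <= d["p"] <= 1 and abs(d["rho"]) <= 1

    def test_planted_edges_recovered(self, config):
        table, truth = simulate.gen_community(config)
        g = net.co_occurrence_network(table, alpha=0.05, p_adjust="bonferroni")
        true_edges = {frozenset(e) for e in
                      zip(truth.edges["taxon_a"], truth.edges["taxon_b"])}
        called = {frozenset(e) for e in g.edges()}
        tp = len(called & true_edges)
        assert tp / len(true_edges) >= 0.9
        assert tp / len(called) >= 0.9


class TestKeystoneFilter:
    def build(self):
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.9, p=0.01, sign="positive")
        g.add_edge("b", "c", rho=0.8, p=0.01, sign="positive")
        g.add_edge("c", "d", rho=-0.7, p=0.01, sign="negative")
        g.add_edge("d", "e", rho=0.6, p=0.01, sign="positive")
        return g

    def test_toy_network_filtered(self):
        g = self.build()
        treatment = {"a": 5, "b": 4, "c": 3, "d": 1, "e": 1}
        control = {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2}
        out = net.keystone_filter(g, treatment, control)
        assert set(out.nodes) == {"a", "b", "c"}
        assert all(d["sign"] == "positive" for _, _, d in out.edges(data=True))

    def test_only_negative_edges_empties_graph(self):
        g = nx.Graph()
        g.add_edge("a", "b", rho=-0.9, p=0.01, sign="negative")
        out = net.keystone_filter(g, {"a": 2, "b": 2}, {"a": 1, "b": 1})
        assert out.number_of_edges() == 0

    def test_all_enriched_keeps_positive_subgraph(self):
        g = self.build()
        up = {v: 2 for v in g}
        down = {v: 1 for v in g}
        out = net.keystone_filter(g, up, down, drop_isolated=False)
        assert set(out.nodes) == set(g.nodes)
        assert out.number_of_edges() == 3

    def test_subgraph_of_positive_subgraph(self, rng, config):
        table, _ = simulate.gen_community(config)
        g = net.co_occurrence_network(table, alpha=0.2)
        treatment = {str(v): float(rng.uniform(0, 2)) for v in g}
        control = {str(v): 1.0 for v in g}
        out = net.keystone_filter(g, treatment, control)
        positive = {frozenset((u, v)) for u, v, d in g.edges(data=True)
                    if d["sign"] == "positive"}
        assert {frozenset(e) for e in out.edges()} <= positive
        assert set(out.nodes) <= {v for v in g if treatment[v] > control[v]}

    def test_missing_control_drops_node(self):
        g = self.build()
        with pytest.warns(UserWarning, match="control"):
            out = net.keystone_filter(g, {v: 2 for v in g},
                                      {v: 1 for v in g if v != "a"})
        assert "a" not in out


class TestTopology:
    def test_complete_graph(self):
        t = net.topology(nx.complete_graph(4))
        assert t.clustering_coefficient == 1.0
        assert t.network_density == 1.0
        assert t.avg_neighbors == 3.0
        assert t.characteristic_path_length == 1.0

    def test_path_graph(self):
        t = net.topology(nx.path_graph(3))
        assert t.clustering_coefficient == 0.0
        assert t.shortest_path_count == 6  # ordered connected pairs

    def test_edgeless_graph(self):
        g = nx.empty_graph(5)
        t = net.topology(g)
        assert t.network_density == 0.0 and t.shortest_path_count == 0

    def test_star_graph_closed_forms(self):
        t = net.topology(nx.star_graph(4))  # hub + 4 leaves
        assert t.network_density == pytest.approx(2 * 4 / (5 * 4))
        assert t.avg_neighbors == pytest.approx(8 / 5)
        assert t.clustering_coefficient == 0.0


class TestMcode:
    def test_clique_with_pendant_chain(self):
        g = nx.complete_graph(5)
        g.add_edges_from([(4, 5), (5, 6), (6, 7)])
        mods = net.mcode(g)
        assert len(mods) == 1
        assert set(mods[0].members) == {0, 1, 2, 3, 4}
        assert mods[0].score == pytest.approx(5.0)

    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        mods = net.mcode(g)
        assert [m.score for m in mods] == [4.0, 4.0]
        assert {frozenset(m.members) for m in mods} == {
            frozenset(range(4)), frozenset(range(4, 8))}

    def test_edgeless_network(self):
        assert net.mcode(nx.empty_graph(4)) == []

    def test_modules_connected_and_consistent(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.35, seed=int(rng.integers(1 << 30)))
            for m in net.mcode(g):
                sub = g.subgraph(m.members)
                assert nx.is_connected(sub)
                assert m.score == pytest.approx(
                    2 * sub.number_of_edges() / max(m.size - 1, 1))

    def test_matches_bitmask_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            g = nx.gnp_random_graph(8, float(rng.uniform(0.2, 0.8)),
                                    seed=int(rng.integers(1 << 30)))
            expected = mcode_modules_oracle(graph_to_masks(g))
            got = [(m.score, frozenset(m.members)) for m in net.mcode(g)]
            assert {(round(s, 9), frozenset(mm)) for s, mm in expected} == \
                {(round(s, 9), m) for s, m in got}


class TestExport:
    @pytest.fixture
    def graph(self, config):
        table, _ = simulate.gen_community(config)
        return net.co_occurrence_network(table, alpha=0.01)

    @pytest.mark.parametrize("fmt", ["edgelist", "graphml"])
    def test_round_trip_with_attributes(self, graph, fmt, tmp_path):
        path = tmp_path / f"net.{fmt}"
        net.export_network(graph, path, fmt)
        back = net.read_network(path, fmt)
        assert {frozenset((str(u), str(v))) for u, v in graph.edges()} == \
            {frozenset((str(u), str(v))) for u, v in back.edges()}
        for u, v, d in graph.edges(data=True):
            d2 = back.edges[str(u), str(v)]
            assert float(d2["rho"]) == pytest.approx(d["rho"])
            assert float(d2["p"]) == pytest.approx(d["p"])
            assert d2["sign"] == d["sign"]

    def test_sif_round_trip_preserves_nodes_and_edges(self, graph, tmp_path):
        path = tmp_path / "net.sif"
        net.export_network(graph, path, "sif")
        back = net.read_network(path, "sif")
        assert {str(v) for v in graph.nodes} == set(back.nodes)
        assert {frozenset((str(u), str(v))) for u, v in graph.edges()} == \
            {frozenset(e) for e in back.edges()}

    def test_empty_network_valid_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        net.export_network(nx.Graph(), path, "edgelist")
        assert net.read_network(path).number_of_edges() == 0

    def test_byte_stable_output(self, tmp_path):
        g = nx.Graph()
        g.add_edge("b", "a", rho=0.5, p=0.01, sign="positive")
        g.add_edge("c", "a", rho=-0.4, p=0.02, sign="negative")
        p1, p2 = tmp_path / "x.tsv", tmp_path / "y.tsv"
        net.export_network(g, p1, "edgelist")
        net.export_network(g, p2, "edgelist")
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            net.export_network(nx.Graph(), tmp_path / "x", "dot")
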