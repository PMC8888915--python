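"""Spearman matrices, edge thresholding, topology metrics, keystones."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from orchardnet.containers import (
    BACTERIAL_KEYSTONE,
    CorrelationMatrix,
    CountMatrix,
    FUNGAL_KEYSTONE,
    KeystoneCriteria,
)
from orchardnet.cooccurrence import (
    CooccurrenceNetwork,
    build_network,
    identify_keystones,
    modularity_partition,
    node_metrics,
    per_stratum_networks,
    spearman_matrix,
    topology_summary,
)

from oracles import brute_graph_metrics, brute_max_modularity, newman_q, random_connected_graph


def matrix_from(X, prefix="t"):
    X = np.asarray(X)
    return CountMatrix([f"{prefix}{i}" for i in range(X.shape[0])],
                       [f"s{j}" for j in range(X.shape[1])], X)


def net_from_edges(edges, nodes):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return CooccurrenceNetwork("test", g, 0.6, 0.05)


class TestSpearman:
    def test_perfect_reversal(self):
        m = matrix_from([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]])
        c = spearman_matrix(m)
        assert c.rho[0, 1] == pytest.approx(-1.0)
        assert c.p[0, 1] == 0.0

    def test_classical_d2_formula_no_ties(self):
        # sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        m = matrix_from([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]])
        c = spearman_matrix(m)
        assert c.rho[0, 1] == pytest.approx(0.8)

    def test_p_from_t_distribution(self):
        # rho = 0.8, n = 5 -> t = 2.3094 on 3 df -> two-sided p ~ 0.104
        m = matrix_from([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]])
        c = spearman_matrix(m)
        t = 0.8 * np.sqrt(3 / (1 - 0.64))
        expect = 2 * stats.t.sf(t, df=3)
        assert c.p[0, 1] == pytest.approx(0.104, abs=2e-3)
        assert c.p[0, 1] == pytest.approx(expect, abs=1e-6)

    def test_zero_variance_taxon_excluded_with_warning(self):
        m = matrix_from([[1, 2, 3, 4, 5], [2, 2, 2, 2, 2], [5, 1, 4, 2, 3]])
        with pytest.warns(UserWarning, match="zero-variance"):
            c = spearman_matrix(m)
        assert c.taxon_ids == ["t0", "t2"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(matrix_from([[1, 2, 3], [3, 2, 1]]))


class TestBuildNetwork:
    def corr3(self, pairs):
        rho = np.eye(3)
        p = np.zeros((3, 3))
        for (i, j), (r, pv) in pairs.items():
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
        return CorrelationMatrix(["a", "b", "c"], rho, p, 10)

    def test_strict_thresholds(self):
        c = self.corr3({(0, 1): (0.9, 0.001), (0, 2): (0.61, 0.01), (1, 2): (0.59, 0.001)})
        net = build_network(c)
        assert net.n_edges == 2
        assert not net.graph.has_edge("b", "c")

    def test_rho_exactly_at_threshold_excluded(self):
        c = self.corr3({(0, 1): (0.6, 0.001)})
        assert build_network(c).n_edges == 0

    def test_significance_gate(self):
        c = self.corr3({(0, 1): (0.9, 0.5), (0, 2): (0.95, 0.5), (1, 2): (0.99, 0.5)})
        net = build_network(c)
        assert net.n_edges == 0 and net.n_nodes == 3

    def test_monotone_filtering(self):
        rng = np.random.default_rng(4)
        k = 8
        r = rng.uniform(-1, 1, (k, k))
        rho = (r + r.T) / 2
        np.fill_diagonal(rho, 1.0)
        pv = rng.uniform(0, 1, (k, k))
        pv = (pv + pv.T) / 2
        np.fill_diagonal(pv, 0.0)
        c = CorrelationMatrix([f"t{i}" for i in range(k)], rho, pv, 30)
        base = set(build_network(c, rho_min=0.3, alpha=0.1).graph.edges)
        tighter_rho = set(build_network(c, rho_min=0.5, alpha=0.1).graph.edges)
        tighter_alpha = set(build_network(c, rho_min=0.3, alpha=0.02).graph.edges)
        assert tighter_rho <= base and tighter_alpha <= base

    def test_config_errors(self):
        c = self.corr3({})
        with pytest.raises(ValueError):
            build_network(c, rho_min=1.5)
        with pytest.raises(ValueError):
            build_network(c, alpha=0.0)


class TestTopology:
    def test_triangle(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")], "abc")
        nm = node_metrics(net).set_index("taxon_id")
        assert (nm["degree"] == 2).all()
        assert (nm["closeness"] == 0.5).all()
        assert (nm["betweenness"] == 0.0).all()
        topo = topology_summary(net)
        assert topo.diameter == 1 and topo.avg_path_length == 1.0
        assert topo.mean_degree == pytest.approx(2.0)

    def test_path_graph(self):
        net = net_from_edges([("a", "b"), ("b", "c")], "abc")
        nm = node_metrics(net).set_index("taxon_id")
        assert nm.loc["b", "betweenness"] == 1.0
        assert nm.loc["b", "closeness"] == 0.5
        assert nm.loc["a", "closeness"] == pytest.approx(1 / 3)
        topo = topology_summary(net)
        assert topo.diameter == 2
        assert topo.avg_path_length == pytest.approx(4 / 3)

    def test_edgeless_graph_undefined_distances(self):
        net = net_from_edges([], "abc")
        topo = topology_summary(net)
        assert topo.diameter is None and topo.avg_path_length is None
        assert topo.modularity is None
        assert topo.n_components == 3

    def test_disconnected_pairs_excluded(self):
        net = net_from_edges([("a", "b"), ("c", "d")], "abcd")
        topo = topology_summary(net)
        assert topo.diameter == 1 and topo.avg_path_length == 1.0
        assert topo.n_components == 2

    @pytest.mark.parametrize("trial", range(4))
    def test_oracle_equivalence_random_graphs(self, trial):
        """Degree/closeness/betweenness/diameter/APL vs brute-force BFS."""
        rng = np.random.default_rng(100 + trial)
        for _ in range(50):
            nodes, edges = random_connected_graph(rng)
            net = net_from_edges(edges, nodes)
            nm = node_metrics(net).set_index("taxon_id")
            ref = brute_graph_metrics(edges, nodes)
            for u in nodes:
                assert nm.loc[u, "degree"] == ref["degree"][u]
                assert nm.loc[u, "closeness"] == ref["closeness"][u]
                assert nm.loc[u, "betweenness"] == pytest.approx(
                    ref["betweenness"][u], abs=1e-12)
            topo = topology_summary(net)
            assert topo.diameter == ref["diameter"]
            assert topo.avg_path_length == pytest.approx(ref["avg_path_length"])


class TestModularity:
    def barbell(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"),
                 ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
        return net_from_edges(edges, "abcdef"), edges

    def test_barbell_reaches_brute_force_maximum(self):
        net, edges = self.barbell()
        part, q = modularity_partition(net, seed=0)
        assert q == pytest.approx(5 / 14, abs=1e-9)
        assert {frozenset(c) for c in part} == {frozenset("abc"), frozenset("def")}
        bq, _ = brute_max_modularity(edges, "abcdef")
        assert q == pytest.approx(bq, abs=1e-9)

    def test_reported_q_is_newman_formula_of_partition(self):
        net, edges = self.barbell()
        part, q = modularity_partition(net, seed=3)
        assert q == pytest.approx(newman_q(edges, [sorted(c) for c in part]), abs=1e-12)

    def test_within_tolerance_of_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            nodes, edges = random_connected_graph(rng, n_max=8)
            net = net_from_edges(edges, nodes)
            _, q = modularity_partition(net, seed=0)
            bq, _ = brute_max_modularity(edges, nodes)
            assert q >= bq - 0.05


class TestKeystones:
    def metrics(self, degree, closeness, betweenness):
        import pandas as pd
        return pd.DataFrame({"taxon_id": ["x"], "degree": [degree],
                             "closeness": [closeness], "betweenness": [betweenness]})

    def test_fungal_thresholds_pass(self):
        assert identify_keystones(self.metrics(6, 0.006, 30), FUNGAL_KEYSTONE) == ["x"]

    @pytest.mark.parametrize("deg,clo,bet", [
        (5, 0.006, 30),      # degree not strictly above 5
        (6, 0.005, 30),      # closeness at threshold
        (6, 0.006, 40),      # betweenness at threshold
    ])
    def test_boundary_values_fail_strictly(self, deg, clo, bet):
        assert identify_keystones(self.metrics(deg, clo, bet), FUNGAL_KEYSTONE) == []

    def test_bacterial_thresholds(self):
        assert identify_keystones(self.metrics(16, 0.04, 20), BACTERIAL_KEYSTONE) == ["x"]
        assert identify_keystones(self.metrics(15, 0.04, 20), BACTERIAL_KEYSTONE) == []

    def test_empty_network_empty_list(self):
        net = net_from_edges([], "ab")
        assert identify_keystones(node_metrics(net), FUNGAL_KEYSTONE) == []

    def test_missing_criteria_field_rejected(self):
        with pytest.raises(Exception):
            KeystoneCriteria(degree_min=5, closeness_min=None, betweenness_max=40)

    def test_output_lexicographic(self):
        import pandas as pd
        nm = pd.DataFrame({"taxon_id": ["z", "a"], "degree": [9, 9],
                           "closeness": [0.1, 0.1], "betweenness": [0.0, 0.0]})
        assert identify_keystones(nm, FUNGAL_KEYSTONE) == ["a", "z"]


class TestPerStratum:
    def test_networks_per_stratum_and_invariance_to_order(self, two_strata_metadata):
        rng = np.random.default_rng(2)
        ids = two_strata_metadata.sample_ids
        m = CountMatrix([f"t{i}" for i in range(6)], ids,
                        rng.integers(0, 50, size=(6, len(ids))))
        nets = per_stratum_networks(m, two_strata_metadata)
        assert set(nets) == {"IPM_drive_row", "grassland"}
        # permuting samples and taxa leaves each stratum's edge set unchanged
        perm_ids = list(reversed(ids))
        perm_taxa = list(reversed(m.taxon_ids))
        m2 = m.select_samples(perm_ids).select_taxa(perm_taxa)
        nets2 = per_stratum_networks(m2, two_strata_metadata)
        for s in nets:
            assert set(map(frozenset, nets[s].graph.edges)) == set(
                map(frozenset, nets2[s].graph.edges))

    def test_single_stratum_equals_direct_build(self, two_strata_metadata):
        rng = np.random.default_rng(3)
        ids = [s for s in two_strata_metadata.sample_ids if s.startswith("grassland")]
        meta = two_strata_metadata.subset(ids)
        m = CountMatrix([f"t{i}" for i in range(5)], ids,
                        rng.integers(0, 40, size=(5, len(ids))))
        nets = per_stratum_networks(m, meta)
        direct = build_network(spearman_matrix(m))
        assert set(nets["grassland"].graph.edges) == set(direct.graph.edges)

    def test_unmapped_sample_is_error(self, two_strata_metadata):
        m = CountMatrix(["t0"], ["mystery_sample"], np.array([[3]]))
        with pytest.raises(KeyError, match="mystery_sample"):
            per_stratum_networks(m, two_strata_metadata)

    def test_small_stratum_is_error(self, two_strata_metadata):
        ids = two_strata_metadata.sample_ids[:6]  # 3 per stratum
        meta = two_strata_metadata.subset(ids)
        m = CountMatrix(["t0", "t1"], ids, np.arange(12).reshape(2, 6))
        with pytest.raises(ValueError, match=">= 4"):
            per_stratum_networks(m, meta)
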