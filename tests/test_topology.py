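"""Network assembly, centrality panel, ranking, pair counts, subnetworks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cernet import (
    TripartiteNetwork,
    ValidationError,
    assemble_network,
    count_pairs,
    extract_subnetwork,
    node_metrics,
    rank_top,
)

from conftest import build_network, make_triplet, random_tripartite


class TestNetworkContract:
    def test_edge_relations_inferred_from_classes(self, toy_network):
        assert ("L", "m1", "lnc_mir") in toy_network.edges()
        assert ("g1", "m1", "mir_mrna") in toy_network.edges()

    def test_same_class_edge_rejected(self):
        net = build_network([], {"a": "miRNA", "b": "miRNA"})
        with pytest.raises(ValidationError, match="miRNA"):
            net.add_edge("a", "b")

    def test_self_loop_and_missing_endpoint_rejected(self):
        net = build_network([], {"a": "miRNA"})
        with pytest.raises(ValidationError, match="self-loop"):
            net.add_edge("a", "a")
        with pytest.raises(ValidationError, match="not a node"):
            net.add_edge("a", "zzz")

    def test_class_relabel_rejected(self):
        net = build_network([], {"a": "miRNA"})
        with pytest.raises(ValidationError, match="relabel"):
            net.add_node("a", "mRNA")


class TestAssemble:
    def test_single_triplet_edge_count(self):
        t = make_triplet("L", "m", "G")
        assert assemble_network([t]).n_edges == 2
        assert assemble_network([t], include_lnc_mrna_edges=True).n_edges == 3
        assert assemble_network([t]).n_nodes == 3

    def test_shared_mirna_union(self):
        trips = [make_triplet("L1", "m", "G1"), make_triplet("L2", "m", "G2")]
        net = assemble_network(trips)
        assert net.n_nodes == 5
        assert net.n_edges == 4

    def test_idempotent_under_duplicates(self):
        t = make_triplet("L", "m", "G")
        net = assemble_network([t, t, t])
        assert (net.n_nodes, net.n_edges) == (3, 2)


class TestNodeMetrics:
    def path_abc(self):
        return build_network(
            [("A", "B"), ("B", "C")],
            {"A": "lncRNA", "B": "miRNA", "C": "mRNA"},
        )

    def test_path_degree_betweenness(self):
        by_id = {m.node_id: m for m in node_metrics(self.path_abc())}
        assert by_id["B"].degree == 2
        assert by_id["B"].betweenness == pytest.approx(1.0)
        assert by_id["A"].betweenness == pytest.approx(0.0)

    def test_path_harmonic_closeness(self):
        by_id = {m.node_id: m for m in node_metrics(self.path_abc())}
        assert by_id["B"].closeness == pytest.approx(1.0)
        assert by_id["A"].closeness == pytest.approx((1 + 0.5) / 2)

    def test_star_pagerank_analytic(self):
        # K1,3: solve the 2-variable fixed point c = 0.15/4 + 0.85*3*l,
        # l = 0.15/4 + 0.85*c/3 analytically
        net = build_network(
            [("c", "l1"), ("c", "l2"), ("c", "l3")],
            {"c": "miRNA", "l1": "lncRNA", "l2": "lncRNA", "l3": "lncRNA"},
        )
        by_id = {m.node_id: m for m in node_metrics(net)}
        center = (0.15 / 4) * (1 + 2.55) / (1 - 0.7225)
        assert by_id["c"].pagerank == pytest.approx(center, abs=1e-9)
        assert by_id["l1"].pagerank == pytest.approx((1 - center) / 3, abs=1e-9)
        assert sum(m.pagerank for m in by_id.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_network_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            node_metrics(TripartiteNetwork())

    def test_degree_sum_is_twice_edges(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            net = random_tripartite(rng, 4, 4, 5, p=0.4)
            metrics = node_metrics(net)
            assert sum(m.degree for m in metrics) == 2 * net.n_edges

    def test_metrics_invariant_under_relabeling(self):
        rng = np.random.default_rng(12)
        net = random_tripartite(rng, 3, 4, 4, p=0.5)
        mapping = {n: f"x_{n}" for n in net.nodes()}
        relabeled = TripartiteNetwork()
        for n in net.nodes():
            relabeled.add_node(mapping[n], net.node_class(n))
        for u, v, _ in net.edges():
            relabeled.add_edge(mapping[u], mapping[v])
        a = {m.node_id: m for m in node_metrics(net)}
        b = {m.node_id: m for m in node_metrics(relabeled)}
        for n in net.nodes():
            ma, mb = a[n], b[mapping[n]]
            assert ma.degree == mb.degree
            assert ma.betweenness == pytest.approx(mb.betweenness, abs=1e-9)
            assert ma.closeness == pytest.approx(mb.closeness, abs=1e-9)
            assert ma.pagerank == pytest.approx(mb.pagerank, abs=1e-9)


class TestRankTop:
    def test_k_at_least_n_returns_everything(self, toy_network):
        metrics = node_metrics(toy_network)
        out = rank_top(metrics, k=50)
        for name, ranked in out["top"].items():
            assert sorted(ranked) == toy_network.nodes()
        assert out["intersection"] == toy_network.nodes()

    def test_ties_broken_lexicographically(self):
        net = build_network(
            [("L", "m1"), ("L", "m2")],
            {"L": "lncRNA", "m1": "miRNA", "m2": "miRNA"},
        )
        out = rank_top(node_metrics(net), k=3)
        assert out["top"]["degree"] == ["L", "m1", "m2"]

    def test_top3_matches_brute_force_sort(self):
        rng = np.random.default_rng(77)
        net = random_tripartite(rng, 4, 4, 4, p=0.5)
        metrics = node_metrics(net)
        out = rank_top(metrics, k=3)
        brute = sorted(metrics, key=lambda m: (-m.degree, m.node_id))[:3]
        assert out["top"]["degree"] == [m.node_id for m in brute]

    def test_class_filter_on_intersection(self, toy_network):
        out = rank_top(node_metrics(toy_network), k=50, class_filter="lncRNA")
        assert out["intersection"] == ["L"]

    def test_invalid_k(self, toy_network):
        with pytest.raises(ValidationError, match="k must be"):
            rank_top(node_metrics(toy_network), k=0)


class TestPairCounts:
    def test_toy_enumeration(self, toy_network):
        rec = count_pairs(toy_network, "L")
        assert (rec.n_first, rec.n_secondary, rec.total) == (2, 3, 5)

    def test_total_is_exact_sum(self):
        from cernet.topology import PairCountRecord

        rec = PairCountRecord("NONHSAT077159", 8, 61)
        assert rec.total == 69

    def test_isolated_lncrna(self):
        net = build_network([], {"L": "lncRNA", "m": "miRNA"})
        rec = count_pairs(net, "L")
        assert (rec.n_first, rec.n_secondary, rec.total) == (0, 0, 0)

    def test_wrong_class_or_unknown_id(self, toy_network):
        with pytest.raises(ValidationError, match="expected lncRNA"):
            count_pairs(toy_network, "m1")
        with pytest.raises(ValidationError, match="unknown node"):
            count_pairs(toy_network, "nope")


class TestSubnetwork:
    def test_toy_seed_recovers_everything(self, toy_network):
        sub = extract_subnetwork(toy_network, "L")
        assert sub == toy_network

    def test_disconnected_triplet_excluded(self, toy_network):
        bigger = toy_network
        bigger.add_node("L2", "lncRNA")
        bigger.add_node("m9", "miRNA")
        bigger.add_node("g9", "mRNA")
        bigger.add_edge("L2", "m9")
        bigger.add_edge("m9", "g9")
        sub = extract_subnetwork(bigger, "L")
        assert "L2" not in sub.nodes() and "g9" not in sub.nodes()

    def test_bfs_depth2_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_tripartite(rng, 3, 4, 5, p=0.35)
            for lnc in net.nodes("lncRNA"):
                sub = extract_subnetwork(net, lnc)
                g = net.graph
                mirs = {
                    v for v in nx.single_source_shortest_path_length(
                        g, lnc, cutoff=1
                    )
                    if g.nodes[v]["class"] == "miRNA"
                }
                depth2 = nx.single_source_shortest_path_length(g, lnc, cutoff=2)
                mrnas = {
                    v for v in depth2
                    if g.nodes[v]["class"] == "mRNA"
                    and any(m in g[v] for m in mirs)
                }
                assert set(sub.nodes()) == {lnc} | mirs | mrnas

    def test_unknown_or_wrong_class(self, toy_network):
        with pytest.raises(ValidationError, match="unknown"):
            extract_subnetwork(toy_network, "nope")
        with pytest.raises(ValidationError, match="not a lncRNA"):
            extract_subnetwork(toy_network, "m1")
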