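import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phosphowrangle.network import (
    AnnotationTable,
    EdgeRecord,
    cluster_network_enrichment,
    expected_edges,
    export_network,
    go_overrepresentation,
    merge_edges,
    random_background,
    read_edge_table,
)


def complete_graph_records(nodes, weight=1.0):
    return [
        EdgeRecord(a, b, weight, database="db")
        for a, b in combinations(sorted(nodes), 2)
    ]


class TestMergeEdges:
    def test_unordered_pair_weights_summed(self):
        net = merge_edges(
            [EdgeRecord("A", "B", 0.5, database="db1"),
             EdgeRecord("B", "A", 0.3, database="db2")]
        )
        assert net.undirected["A"]["B"]["weight"] == pytest.approx(0.8)
        assert net.undirected["A"]["B"]["databases"] == "db1,db2"

    def test_kinase_substrate_edge_gets_fixed_weight(self):
        net = merge_edges([EdgeRecord("A", "B", 0.9, directed=True)])
        assert net.directed["A"]["B"]["weight"] == pytest.approx(0.25)
        assert net.undirected.number_of_edges() == 0

    def test_weight_conservation_random_table(self):
        rng = np.random.default_rng(0)
        nodes = [f"G{i}" for i in range(12)]
        records = []
        for _ in range(50):
            a, b = rng.choice(nodes, size=2, replace=False)
            records.append(
                EdgeRecord(a, b, float(rng.uniform(0, 2)),
                           directed=bool(rng.random() < 0.3))
            )
        net = merge_edges(records)
        expected = sum(
            0.25 if r.directed else r.weight for r in records
        )
        assert net.total_weight() == pytest.approx(expected)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        nodes = [f"G{i}" for i in range(8)]
        records = [
            EdgeRecord(*rng.choice(nodes, size=2, replace=False),
                       float(rng.uniform(0, 1)))
            for _ in range(30)
        ]
        net1 = merge_edges(records)
        net2 = merge_edges(records[::-1])
        for u, v, d in net1.undirected.edges(data=True):
            assert net2.undirected[u][v]["weight"] == pytest.approx(d["weight"])
        assert net1.n_edges() == net2.n_edges()

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            merge_edges([EdgeRecord("A", "A", 1.0)])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            EdgeRecord("A", "B", -1.0)

    def test_pair_evidence_sums_both_classes(self):
        net = merge_edges(
            [EdgeRecord("A", "B", 0.5), EdgeRecord("A", "B", 0.1, directed=True)]
        )
        assert net.pair_evidence("A", "B") == pytest.approx(0.75)


class TestRandomBackground:
    def test_edgeless_network_all_zero(self):
        net = merge_edges([EdgeRecord("X", "Y", 1.0)])
        net.undirected.remove_edge("X", "Y")
        bg = random_background(
            net, [f"G{i}" for i in range(40)], size_min=3, size_max=6, seed=0
        )
        assert bg.mean_edges_per_node == 0.0
        assert bg.mean_weight_per_node == 0.0

    def test_complete_graph_closed_form(self):
        # every size-n subset of a complete unit graph induces C(n,2) edges
        nodes = [f"G{i}" for i in range(12)]
        net = merge_edges(complete_graph_records(nodes))
        bg = random_background(net, nodes, size_min=3, size_max=5,
                               reps_per_size=2, seed=1)
        expected = np.mean([(n - 1) / 2 for n in (3, 3, 4, 4, 5, 5)])
        assert bg.mean_edges_per_node == pytest.approx(expected)

    def test_seed_reproducibility(self):
        nodes = [f"G{i}" for i in range(30)]
        net = merge_edges(complete_graph_records(nodes[:10]))
        bg1 = random_background(net, nodes, size_min=4, size_max=8, seed=9)
        bg2 = random_background(net, nodes, size_min=4, size_max=8, seed=9)
        assert bg1 == bg2

    def test_default_sizes_give_48_sets(self):
        nodes = [f"G{i}" for i in range(50)]
        net = merge_edges(complete_graph_records(nodes[:5]))
        bg = random_background(net, nodes, seed=0)
        assert bg.n_sets == 48

    def test_size_exceeding_universe_rejected(self):
        net = merge_edges([EdgeRecord("A", "B", 1.0)])
        with pytest.raises(ValueError, match="universe"):
            random_background(net, ["A", "B", "C"], size_min=2, size_max=5)

    def test_erdos_renyi_mean_converges_to_expectation(self):
        rng = np.random.default_rng(5)
        nodes = [f"G{i}" for i in range(40)]
        p = 0.2
        records = [
            EdgeRecord(a, b, 1.0)
            for a, b in combinations(nodes, 2) if rng.random() < p
        ]
        net = merge_edges(records)
        E = net.undirected.number_of_edges()
        n_uni = len(nodes)
        bg = random_background(net, nodes, size_min=10, size_max=10,
                               reps_per_size=400, seed=3)
        # expected induced edges for a size-10 subset: E * C(10,2)/C(40,2)
        exp_epn = E * math.comb(10, 2) / math.comb(n_uni, 2) / 10
        se = bg.sd_edges_per_node / math.sqrt(bg.n_sets)
        assert abs(bg.mean_edges_per_node - exp_epn) < 3 * se


class TestEnrichment:
    def test_cluster_like_background_folds_near_one(self):
        nodes = [f"G{i}" for i in range(20)]
        net = merge_edges(complete_graph_records(nodes))
        bg = random_background(net, nodes, size_min=10, size_max=10,
                               reps_per_size=5, seed=0)
        out = cluster_network_enrichment(nodes[:10], net, bg)
        assert out["edge_fold"] == pytest.approx(1.0)
        assert out["weight_fold"] == pytest.approx(1.0)

    def test_edge_fold_arithmetic(self):
        # 10-node cluster with 13 induced unit edges vs background 0.065/node
        nodes = [f"G{i}" for i in range(10)]
        records = complete_graph_records(nodes)[:13]
        net = merge_edges(records)
        from phosphowrangle.network import BackgroundStats

        bg = BackgroundStats(
            size_min=11, size_max=34, reps_per_size=2, seed=0,
            mean_edges_per_node=0.065, sd_edges_per_node=0.1,
            mean_weight_per_node=0.002, sd_weight_per_node=0.01,
        )
        out = cluster_network_enrichment(nodes, net, bg)
        assert out["edge_fold"] == pytest.approx(1.3 / 0.065)

    def test_edgeless_cluster_zero_fold(self):
        nodes = [f"G{i}" for i in range(6)]
        net = merge_edges(complete_graph_records(nodes[:4]))
        bg = random_background(net, nodes, size_min=3, size_max=4, seed=2)
        out = cluster_network_enrichment(["G4", "G5"], net, bg)
        assert out["edge_fold"] == 0.0


class TestExpectedEdges:
    def test_density_model_formula(self):
        # N=5 nodes, E=4 edges, cluster of 3: 4 * 3/10 = 1.2
        records = [
            EdgeRecord("A", "B", 1), EdgeRecord("B", "C", 1),
            EdgeRecord("C", "D", 1), EdgeRecord("D", "E", 1),
        ]
        net = merge_edges(records)
        out = expected_edges(["A", "B", "C"], net, model="density")
        assert out["expected"] == pytest.approx(1.2)
        assert out["observed"] == 2

    def test_whole_network_expected_equals_total(self):
        nodes = ["A", "B", "C", "D"]
        net = merge_edges(complete_graph_records(nodes))
        out = expected_edges(nodes, net, model="density")
        assert out["expected"] == pytest.approx(net.undirected.number_of_edges())

    def test_configuration_model_star_graph(self):
        # K_{1,4}: two leaves have k=1 each, E=4 -> 1*1/(2*4) = 0.125
        records = [EdgeRecord("HUB", leaf, 1.0) for leaf in "ABCD"]
        net = merge_edges(records)
        out = expected_edges(["A", "B"], net, model="configuration")
        assert out["expected"] == pytest.approx(0.125)


def exact_hypergeom_tail(N, K, n, k):
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestGoOverrepresentation:
    def annotation(self, n_genes=20, term_sizes={"T1": 5}):
        universe = [f"G{i}" for i in range(n_genes)]
        rows = {}
        for term, size in term_sizes.items():
            for g in universe[:size]:
                rows.setdefault(g, set()).add(term)
        return AnnotationTable(
            gene_terms={g: frozenset(t) for g, t in rows.items()},
            term_names={t: t.lower() for t in term_sizes},
            universe=tuple(universe),
        )

    def test_hand_example_not_retained(self):
        # universe 20, term 5, cluster 5, overlap 3: p = 1126/15504
        annot = self.annotation()
        cluster = ["G0", "G1", "G2", "G10", "G11"]
        res = go_overrepresentation(cluster, annot, alpha=0.01)
        r = next(x for x in res if x.term == "T1")
        assert r.p_value == pytest.approx(1126 / 15504, abs=1e-12)
        assert not r.retained

    def test_single_hit_discarded_even_if_significant(self):
        annot = self.annotation(n_genes=1000, term_sizes={"T1": 1})
        res = go_overrepresentation(["G0", "G999"], annot, alpha=0.05)
        r = next(x for x in res if x.term == "T1")
        assert r.p_value < 0.01 and not r.retained

    def test_term_covering_universe_not_retained(self):
        annot = self.annotation(n_genes=10, term_sizes={"T1": 10})
        res = go_overrepresentation(["G0", "G1"], annot, alpha=0.01)
        r = res[0]
        assert r.p_value == pytest.approx(1.0)
        assert not r.retained

    def test_matches_exact_enumeration_on_small_universes(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            N = int(rng.integers(8, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(2, N + 1))
            annot = self.annotation(n_genes=N, term_sizes={"T1": K})
            cluster = list(rng.choice([f"G{i}" for i in range(N)], n, replace=False))
            res = go_overrepresentation(cluster, annot, alpha=0.01)
            k = len({f"G{i}" for i in range(K)} & set(cluster))
            if k == 0:
                assert not any(r.term == "T1" for r in res)
            else:
                r = next(x for x in res if x.term == "T1")
                assert abs(r.p_value - exact_hypergeom_tail(N, K, n, k)) < 1e-12

    def test_empty_universe_rejected(self):
        annot = AnnotationTable(gene_terms={}, term_names={}, universe=())
        with pytest.raises(ValueError):
            go_overrepresentation([], annot)


class TestExport:
    def make_net(self):
        return merge_edges(
            [
                EdgeRecord("A", "B", 0.5, database="db1"),
                EdgeRecord("B", "C", 1.5, database="db2"),
                EdgeRecord("A", "C", 0.7, directed=True),
            ]
        )

    def test_tsv_roundtrip_preserves_edges_and_weights(self, tmp_path):
        net = self.make_net()
        p = tmp_path / "net.tsv"
        export_network(net, p, "tsv")
        back = merge_edges(read_edge_table(p))
        # directed edges re-enter at psp_weight; undirected weights exact
        assert back.undirected["A"]["B"]["weight"] == pytest.approx(0.5)
        assert back.undirected["B"]["C"]["weight"] == pytest.approx(1.5)
        assert back.directed.has_edge("A", "C")

    def test_directed_edge_flagged_in_graphml(self, tmp_path):
        import networkx as nx

        p = tmp_path / "net.graphml"
        export_network(self.make_net(), p, "graphml")
        g = nx.read_graphml(p)
        assert g["A"]["C"]["directed"] is True
        assert g["A"]["B"]["directed"] is False

    def test_byte_stable_output(self, tmp_path):
        p1, p2 = tmp_path / "a.sif", tmp_path / "b.sif"
        export_network(self.make_net(), p1, "sif")
        export_network(self.make_net(), p2, "sif")
        assert p1.read_bytes() == p2.read_bytes()

    def test_node_attribute_from_matrix(self, tmp_path, dense_matrix):
        import networkx as nx

        net = merge_edges(
            [EdgeRecord(dense_matrix.genes[0], dense_matrix.genes[1], 1.0)]
        )
        p = tmp_path / "net.graphml"
        export_network(
            net, p, "graphml",
            total_phosphorylation=dense_matrix.total_phosphorylation(),
        )
        g = nx.read_graphml(p)
        g0 = dense_matrix.genes[0]
        assert g.nodes[g0]["total_phosphorylation"] == pytest.approx(
            dense_matrix.total_phosphorylation()[g0]
        )

    def test_empty_network_rejected(self, tmp_path):
        net = merge_edges([EdgeRecord("A", "B", 1.0)])
        net.undirected.remove_edge("A", "B")
        with pytest.raises(ValueError, match="empty"):
            export_network(net, tmp_path / "x.tsv", "tsv")
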