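"""SSN construction rules and topology statistics vs brute-force oracles."""

import math
import random

import networkx as nx
import pytest

import ssn_divergence as sd
from oracles import graph_stats


def make_hit(a, b, evalue, bitscore=50.0, pident=90.0):
    return sd.AlignmentHit(
        query_id=a,
        subject_id=b,
        raw_score=0,
        pct_identity=pident,
        aln_len=10,
        n_mismatch=1,
        n_gap_opens=0,
        q_start=1,
        q_end=10,
        s_start=1,
        s_end=10,
        evalue=evalue,
        bitscore=bitscore,
    )


def rec(rid, fam="f", hab="mat", seq="MKVLINGKTLKG"):
    return sd.ProteinRecord(rid, fam, hab, seq)


class TestLengthFilter:
    def test_strictly_greater_than_cutoff(self):
        records = [
            sd.ProteinRecord("a", "f", "mat", "A" * 150),
            sd.ProteinRecord("b", "f", "mat", "A" * 151),
        ]
        kept = sd.length_filter(records, 150)
        assert [r.id for r in kept] == ["b"]

    def test_zero_cutoff_keeps_all(self):
        records = [sd.ProteinRecord("a", "f", "mat", "MK")]
        assert sd.length_filter(records, 0) == records

    def test_empty_input(self):
        assert sd.length_filter([], 150) == []


class TestBuildNetwork:
    def test_threshold_filters_edges(self):
        records = [rec("a"), rec("b"), rec("c")]
        hits = [make_hit("a", "b", 1e-40), make_hit("b", "c", 1e-10)]
        net = sd.build_network(records, hits, threshold=1e-30)
        assert net.number_of_edges() == 1
        assert len(sd.isolated_nodes(net)) == 1

    def test_reciprocal_hits_collapse_to_min_evalue(self):
        records = [rec("a"), rec("b")]
        hits = [
            make_hit("a", "b", 1e-40, bitscore=100.0),
            make_hit("b", "a", 1e-50, bitscore=120.0),
        ]
        net = sd.build_network(records, hits, threshold=1e-30)
        assert net.number_of_edges() == 1
        assert net.edges["a", "b"]["evalue"] == 1e-50
        assert net.edges["a", "b"]["bitscore"] == 120.0

    def test_infinite_threshold_keeps_all_pairs(self):
        records = [rec(x) for x in "abcd"]
        hits = [make_hit("a", "b", 0.5), make_hit("c", "d", 2.0), make_hit("a", "c", 9.0)]
        net = sd.build_network(records, hits, threshold=math.inf)
        assert net.number_of_edges() == 3

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sd.build_network([rec("a")], [make_hit("a", "zz", 1e-40)])

    def test_tightening_threshold_monotone(self):
        """Smaller e-value cutoffs never decrease component/isolated counts."""
        rng = random.Random(5)
        records = [rec(f"n{i}") for i in range(12)]
        hits = [
            make_hit(f"n{rng.randrange(12)}", f"n{rng.randrange(12)}", 10 ** -rng.randint(10, 60))
            for _ in range(30)
        ]
        hits = [h for h in hits if h.query_id != h.subject_id]
        prev_comp, prev_iso = 0, 0
        for exponent in (20, 30, 40, 50, 70):
            net = sd.build_network(records, hits, threshold=10**-exponent)
            topo = sd.global_topology(net)
            assert topo.n_components >= prev_comp
            assert topo.n_isolated >= prev_iso
            prev_comp, prev_iso = topo.n_components, topo.n_isolated


class TestComponents:
    def test_triangle_plus_lone_node(self):
        records = [rec(x) for x in "abcd"]
        hits = [make_hit("a", "b", 1e-40), make_hit("b", "c", 1e-40), make_hit("a", "c", 1e-40)]
        net = sd.build_network(records, hits)
        comps = sd.connected_components(net)
        assert len(comps) == 2
        assert sd.isolated_nodes(net) == {"d"}

    def test_no_edges_all_isolated(self):
        records = [rec(f"n{i}") for i in range(5)]
        net = sd.build_network(records, [])
        assert len(sd.connected_components(net)) == 5
        assert len(sd.isolated_nodes(net)) == 5

    def test_matches_transitive_closure_oracle(self):
        rng = random.Random(11)
        for _ in range(40):
            n = rng.randint(1, 12)
            edges = [
                (rng.randrange(n), rng.randrange(n))
                for _ in range(rng.randint(0, 2 * n))
            ]
            net = nx.Graph()
            net.add_nodes_from(range(n))
            net.add_edges_from((u, v) for u, v in edges if u != v)
            expected = graph_stats(n, edges)["components"]
            got = sd.connected_components(net)
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


class TestGlobalTopology:
    def test_published_scale_identities(self):
        """average degree = 2K/N and density = 2K/(N(N-1)) on a network of
        2,413 nodes and 162,389 edges print (truncated) as 134.59 and 0.05."""
        net = nx.gnm_random_graph(2413, 162389, seed=0)
        topo = sd.global_topology(net, detailed=False)
        assert math.trunc(topo.avg_degree * 100) / 100 == 134.59
        assert math.trunc(topo.density * 100) / 100 == 0.05

    def test_triangle_is_fully_connected(self):
        net = nx.complete_graph(3)
        topo = sd.global_topology(net)
        assert topo.avg_degree == 2
        assert topo.density == 1
        assert topo.avg_clustering == 1
        assert topo.char_path_length == 1
        assert topo.centralization == 0
        assert topo.connected_pair_pct == 100.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            sd.global_topology(nx.Graph())

    def test_formula_identities_on_random_graphs(self):
        rng = random.Random(23)
        for _ in range(20):
            net = nx.gnm_random_graph(rng.randint(2, 30), rng.randint(0, 60), seed=rng.randrange(10**6))
            topo = sd.global_topology(net, detailed=False)
            n, k = topo.n_nodes, topo.n_edges
            assert topo.avg_degree * n == pytest.approx(2 * k)
            assert topo.density * n * (n - 1) == pytest.approx(2 * k)
            assert topo.n_isolated <= topo.n_components <= n


class TestNodeMetrics:
    def test_path_graph_closeness(self):
        net = nx.path_graph(["a", "b", "c"])
        metrics = sd.node_metrics(net)
        assert metrics.loc["b", "closeness"] == pytest.approx(1.0)
        assert metrics.loc["a", "closeness"] == pytest.approx(2 / 3)

    def test_triangle_metrics(self):
        net = nx.complete_graph(3)
        metrics = sd.node_metrics(net)
        assert (metrics["clustering"] == 1).all()
        assert (metrics["neighborhood_connectivity"] == 2).all()

    def test_all_metrics_match_floyd_warshall_oracle(self):
        """Degree, clustering, neighborhood connectivity, closeness and every
        global statistic agree with direct brute-force computation on 200
        random graphs."""
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(1, 12)
            edges = [
                (rng.randrange(n), rng.randrange(n))
                for _ in range(rng.randint(0, 3 * n))
            ]
            net = nx.Graph()
            net.add_nodes_from(range(n))
            net.add_edges_from((u, v) for u, v in edges if u != v)
            expected = graph_stats(n, edges)
            topo = sd.global_topology(net)
            for field in (
                "n_nodes",
                "n_edges",
                "avg_degree",
                "density",
                "n_components",
                "n_isolated",
                "avg_clustering",
                "char_path_length",
                "connected_pair_pct",
                "centralization",
            ):
                assert getattr(topo, field) == pytest.approx(expected[field]), field
            metrics = sd.node_metrics(net)
            for node in range(n):
                assert metrics.loc[node, "degree"] == expected["degree"][node]
                assert metrics.loc[node, "clustering"] == pytest.approx(
                    expected["clustering"][node]
                )
                assert metrics.loc[node, "neighborhood_connectivity"] == pytest.approx(
                    expected["neighborhood_connectivity"][node]
                )
                assert metrics.loc[node, "closeness"] == pytest.approx(
                    expected["closeness"][node]
                )


class TestGreedyCluster:
    def _records(self, seqs):
        return [sd.ProteinRecord(f"s{i}", "f", "mat", s) for i, s in enumerate(seqs)]

    def test_identical_sequences_merge_at_100(self):
        records = self._records(["MKVLING", "MKVLING"])
        hits = sd.all_vs_all(records)
        assignment = sd.greedy_cluster(records, hits, 100.0)
        assert len(set(assignment.values())) == 1

    def test_distinct_sequences_stay_apart_at_100(self):
        records = self._records(["MKVLING", "MKWHING", "AAPPLES"])
        hits = sd.all_vs_all(records)
        assignment = sd.greedy_cluster(records, hits, 100.0)
        assert len(set(assignment.values())) == 3

    def test_cluster_count_monotone_in_threshold(self):
        rng = random.Random(17)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(rng.choice(aas) for _ in range(40))
        seqs = []
        for _ in range(8):
            s = list(base)
            for _ in range(rng.randint(0, 15)):
                s[rng.randrange(40)] = rng.choice(aas)
            seqs.append("".join(s))
        records = self._records(seqs)
        hits = sd.all_vs_all(records)
        counts = [
            len(set(sd.greedy_cluster(records, hits, t).values()))
            for t in (100.0, 90.0, 75.0, 50.0, 25.0)
        ]
        assert counts == sorted(counts, reverse=True)
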