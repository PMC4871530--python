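"""Co-occurrence network construction, topology and comparison."""

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from otunet import networks as nw
from otunet.tables_io import OtuTable


def _table(counts: dict, groups=None) -> OtuTable:
    df = pd.DataFrame(counts)
    df.index = [f"s{i}" for i in range(len(df))]
    meta = pd.DataFrame(
        {"group": groups or ["g"] * len(df), "tank": ["t"] * len(df)}, index=df.index
    )
    return OtuTable(df, meta)


def _records(rows):
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "q"])


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        t = _table({"up": [1, 2, 3, 4, 5], "up2": [2, 4, 6, 9, 11], "down": [9, 7, 5, 3, 1]})
        rec = nw.spearman_matrix(t).set_index(["otu_a", "otu_b"])
        assert rec.loc[("up", "up2"), "rho"] == pytest.approx(1.0)
        assert rec.loc[("up", "down"), "rho"] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # ranks (1..5) vs (2,1,4,3,5): sum d^2 = 4 -> rho = 1 - 24/120 = 0.8
        t = _table({"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5], "c": [5, 1, 4, 2, 3]})
        rec = nw.spearman_matrix(t).set_index(["otu_a", "otu_b"])
        assert rec.loc[("a", "b"), "rho"] == pytest.approx(0.8)

    def test_constant_otus_skipped(self):
        t = _table({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1], "const": [7, 7, 7, 7]})
        rec = nw.spearman_matrix(t)
        assert not (rec[["otu_a", "otu_b"]] == "const").any().any()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nw.spearman_matrix(_table({"a": [1, 2, 3], "b": [3, 2, 1]}))


class TestBuildNetwork:
    def test_threshold_filtering(self):
        rec = _records(
            [
                ("a", "b", 0.45, 0.001, 0.01),  # weak rho
                ("a", "c", 0.90, 0.010, 0.25),  # q too high
                ("b", "c", 0.60, 0.200, 0.01),  # p too high
                ("c", "d", -0.70, 0.010, 0.05),  # kept, negative
            ]
        )
        net = nw.build_network(rec)
        assert set(net.edges) == {("c", "d")}
        assert net.edges["c", "d"]["sign"] == "negative"
        # isolated OTUs never become vertices
        assert set(net.nodes) == {"c", "d"}

    def test_duplicate_and_self_records_trimmed(self):
        rec = _records(
            [
                ("a", "b", 0.9, 0.001, 0.01),
                ("b", "a", 0.9, 0.001, 0.01),
                ("a", "a", 1.0, 0.000, 0.00),
            ]
        )
        net = nw.build_network(rec)
        assert net.number_of_edges() == 1

    def test_invariant_to_record_ordering(self):
        rows = [
            ("a", "b", 0.9, 0.001, 0.01),
            ("b", "c", -0.8, 0.002, 0.02),
            ("c", "d", 0.7, 0.003, 0.03),
        ]
        n1 = nw.build_network(_records(rows))
        n2 = nw.build_network(_records(rows[::-1]))
        assert nx.utils.graphs_equal(n1, n2)

    def test_zero_surviving_edges_is_valid_empty_network(self):
        net = nw.build_network(_records([("a", "b", 0.1, 0.9, 0.9)]))
        assert net.number_of_nodes() == 0
        summ = nw.network_summary(net)
        assert summ.vertices == summ.total_edges == 0


def _brute_betweenness(g: nx.Graph) -> dict:
    """Shortest-path enumeration oracle, independent of Brandes."""

    def shortest_paths(s, t):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        if t not in dist:
            return []
        paths = []

        def dfs(u, path):
            if u == t:
                paths.append(path)
                return
            for w in g.neighbors(u):
                if dist.get(w, -1) == dist[u] + 1 and dist[w] <= dist[t]:
                    dfs(w, path + [w])

        dfs(s, [s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    n = g.number_of_nodes()
    bc = {v: 0.0 for v in g.nodes}
    for s, t in combinations(g.nodes, 2):
        paths = shortest_paths(s, t)
        if not paths:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in paths) / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: b / norm for v, b in bc.items()} if norm > 0 else bc


class TestBetweenness:
    def test_path_graph(self):
        g = nx.path_graph(["a", "b", "c"])
        bc = nw.betweenness(g)
        assert bc["b"] == pytest.approx(1.0)
        assert bc["a"] == bc["c"] == 0.0

    def test_complete_graph_all_zero(self):
        assert (nw.betweenness(nx.complete_graph(4)) == 0).all()

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(2**31)))
            ours = nw.betweenness(g)
            oracle = _brute_betweenness(g)
            for v in g.nodes:
                assert ours[v] == pytest.approx(oracle[v], abs=1e-12)

    def test_empty_network(self):
        assert nw.betweenness(nx.Graph()).empty


class TestCommunities:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        comms = nw.greedy_communities(g)
        assert len(comms) == 2
        assert {frozenset(c) for c in comms} == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_two_cliques_with_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        comms = nw.greedy_communities(g)
        assert len(comms) == 2

    def test_communities_respect_components(self):
        g = nx.gnp_random_graph(20, 0.1, seed=4)
        comps = list(nx.connected_components(g))
        for comm in nw.greedy_communities(g):
            assert any(comm <= comp for comp in comps)


class TestSummaryAndComparison:
    def _net(self, edges):
        g = nx.Graph()
        for a, b, rho in edges:
            g.add_edge(a, b, rho=rho, p=0.001, q=0.01,
                       sign="positive" if rho > 0 else "negative")
        return g

    def test_mean_degree_identity(self):
        g = self._net([("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", -0.7)])
        summ = nw.network_summary(g)
        assert summ.mean_degree == pytest.approx(2 * summ.total_edges / summ.vertices)
        assert summ.positive_edges + summ.negative_edges == summ.total_edges
        assert summ.vertices_with_negative_edge == 2
        assert summ.pct_vertices_with_negative_edge == pytest.approx(50.0)

    def test_identical_networks_compare_as_equal(self):
        g = self._net([("a", "b", 0.9), ("b", "c", -0.8)])
        rep = nw.compare_networks(g, g.copy())
        assert rep["fisher_p"] == pytest.approx(1.0)
        assert rep["fisher_odds_ratio"] == pytest.approx(1.0)
        assert rep["degree_mw_p"] == pytest.approx(1.0)
        assert rep["shared_vertices"] == 3
        assert rep["unique_to_a"] == rep["unique_to_b"] == 0

    def test_balanced_sign_table_odds_ratio_one(self):
        a = nw.NetworkSummary(None, 20, 20, 10, 10, 2.0, 0.0, 0, 0, 0, 0, 1)
        b = nw.NetworkSummary(None, 20, 20, 10, 10, 2.0, 0.0, 0, 0, 0, 0, 1)
        odds, p = nw.edge_sign_fisher(a, b)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_venn_counts_partition_vertices(self, filtered_study):
        table, _ = filtered_study
        nets = nw.group_networks(table)
        venn = nw.venn_counts(nets)
        all_vertices = set().union(*(n.nodes for n in nets.values()))
        assert sum(venn.values()) == len(all_vertices)


class TestPlantedRecovery:
    def test_strong_planted_pairs_recovered(self, filtered_study):
        table, truth = filtered_study
        nets = nw.group_networks(table)
        planted = {
            tuple(sorted((r.otu_a, r.otu_b))): np.sign(r.true_rho)
            for r in truth.pairs.itertuples()
        }
        recovered, agree, total = 0, 0, 0
        for net in nets.values():
            edges = {tuple(sorted(e)) for e in net.edges}
            for pair, sign in planted.items():
                total += 1
                if pair in edges:
                    recovered += 1
                    agree += np.sign(net.edges[pair]["rho"]) == sign
        assert recovered / total >= 0.8
        assert agree / recovered >= 0.95
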