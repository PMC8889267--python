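"""Tests for coexpression list handling and network builders."""

import itertools

import networkx as nx
import numpy as np
import pytest

from clptrap import coexnet as cx


def lists_from(mapping):
    """mapping: bait -> [(gene, ls), ...]"""
    return {b: cx.CoexprList.build(b, pairs) for b, pairs in mapping.items()}


def random_lists(rng, n_baits=8, n_genes=60, n_entries=25):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    baits = [f"B{i}" for i in range(n_baits)]
    out = {}
    for b in baits:
        chosen = rng.choice(genes, size=n_entries, replace=False)
        out[b] = cx.CoexprList.build(
            b, [(g, float(rng.normal(5, 2))) for g in chosen])
    return out, baits


class TestLoadCoexpression:
    def test_parses_and_sorts(self, tmp_path):
        path = tmp_path / "coex.tsv"
        path.write_text("bait\tgene\tLS\n"
                        "B1\tG1\t2.0\nB1\tG2\t7.5\nB2\tG1\t4.0\n")
        lists = cx.load_coexpression(path)
        assert set(lists) == {"B1", "B2"}
        assert lists["B1"].entries == (("G2", 7.5), ("G1", 2.0))

    def test_truncates_to_cap(self, tmp_path):
        rows = "".join(f"B1\tG{i:03d}\t{150 - i}\n" for i in range(150))
        path = tmp_path / "coex.tsv"
        path.write_text("bait\tgene\tLS\n" + rows)
        lists = cx.load_coexpression(path)
        assert len(lists["B1"].entries) == 100
        assert lists["B1"].entries[0] == ("G000", 150.0)

    def test_non_numeric_ls_raises_with_row(self, tmp_path):
        path = tmp_path / "coex.tsv"
        path.write_text("bait\tgene\tLS\nB1\tG1\t3.0\nB1\tG2\tbogus\n")
        with pytest.raises(ValueError, match="row 2"):
            cx.load_coexpression(path)

    def test_duplicate_entry_keeps_max_with_warning(self, tmp_path):
        path = tmp_path / "coex.tsv"
        path.write_text("bait\tgene\tLS\nB1\tG1\t3.0\nB1\tG1\t5.0\n")
        with pytest.warns(UserWarning):
            lists = cx.load_coexpression(path)
        assert lists["B1"].entries == (("G1", 5.0),)

    def test_bait_never_lists_itself(self):
        cl = cx.CoexprList.build("B1", [("B1", 9.0), ("G1", 2.0)])
        assert cl.entries == (("G1", 2.0),)


class TestTopK:
    def test_disjoint_topk_counts(self):
        lists = lists_from({
            "B1": [("G1", 5), ("G2", 4), ("G3", 3)],
            "B2": [("G4", 5), ("G5", 4), ("G6", 3)],
        })
        net = cx.top_k_network(lists, k=2)
        assert net.number_of_edges() == 4 and net.number_of_nodes() == 6

    def test_reciprocal_bait_edge_deduplicated(self):
        lists = lists_from({
            "B1": [("B2", 5), ("G1", 4)],
            "B2": [("B1", 6), ("G2", 4)],
        })
        net = cx.top_k_network(lists, k=2)
        assert net.number_of_edges() == 3
        assert net.edges[("B1", "B2")]["ls"] == 6  # max over directions

    def test_tie_at_rank_k_breaks_lexicographically(self):
        lists = lists_from({"B1": [("GB", 5.0), ("GA", 3.0), ("GC", 3.0)]})
        net = cx.top_k_network(lists, k=2)
        assert set(net.nodes) == {"B1", "GB", "GA"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lists, baits = random_lists(rng)
        net = cx.top_k_network(lists, k=10, baits=baits)
        oracle = set()
        for b in baits:
            for g, _ in sorted(lists[b].entries,
                               key=lambda kv: (-kv[1], kv[0]))[:10]:
                oracle.add(frozenset((b, g)))
        assert {frozenset(e) for e in net.edges} == oracle

    def test_growing_k_grows_edges(self):
        rng = np.random.default_rng(7)
        lists, baits = random_lists(rng)
        e5 = {frozenset(e) for e in cx.top_k_network(lists, 5, baits).edges}
        e15 = {frozenset(e) for e in cx.top_k_network(lists, 15, baits).edges}
        assert e5 <= e15


class TestThreshold:
    def test_all_below_threshold_empty(self):
        lists = lists_from({"B1": [("G1", 2.0)], "B2": [("G2", 1.0)]})
        net = cx.threshold_network(lists, 6.0)
        assert net.number_of_edges() == 0 and net.number_of_nodes() == 0

    def test_minus_infinity_equals_full_union(self):
        rng = np.random.default_rng(1)
        lists, baits = random_lists(rng)
        thr = cx.threshold_network(lists, -np.inf, baits)
        full = cx.top_k_network(lists, k=100, baits=baits)
        assert {frozenset(e) for e in thr.edges} == \
            {frozenset(e) for e in full.edges}

    def test_threshold_inclusive(self):
        lists = lists_from({"B1": [("G1", 6.0), ("G2", 5.999)]})
        net = cx.threshold_network(lists, 6.0)
        assert set(net.nodes) == {"B1", "G1"}

    @pytest.mark.parametrize("seed", range(10))
    def test_nested_thresholds_nest_edge_sets(self, seed):
        rng = np.random.default_rng(50 + seed)
        lists, baits = random_lists(rng)
        lo = {frozenset(e)
              for e in cx.threshold_network(lists, 4.0, baits).edges}
        hi = {frozenset(e)
              for e in cx.threshold_network(lists, 6.5, baits).edges}
        assert hi <= lo


class TestCombined:
    def test_degree_two_coexpressor_retained(self):
        lists = lists_from({
            "B1": [("G1", 7.0), ("G2", 1.0)],
            "B2": [("G1", 6.5), ("G3", 1.0)],
        })
        net = cx.combined_min_degree_network(lists, k=1, ls_min=6.0)
        assert "G1" in net and net.degree("G1") == 2

    def test_degree_one_coexpressor_removed(self):
        lists = lists_from({
            "B1": [("G1", 7.0), ("G2", 6.5)],
            "B2": [("G3", 7.0), ("G1", 6.5)],
        })
        net = cx.combined_min_degree_network(lists, k=2, ls_min=6.0)
        assert "G2" not in net and "G3" not in net and "G1" in net

    def test_baits_with_no_surviving_edges_drop(self):
        lists = lists_from({
            "B1": [("G1", 7.0)],
            "B2": [("G2", 7.0)],
            "B3": [("G3", 7.0), ("G4", 6.5)],
        })
        net = cx.combined_min_degree_network(lists, k=1, ls_min=6.0)
        assert set(net.nodes) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_single_pass_oracle(self, seed):
        rng = np.random.default_rng(80 + seed)
        lists, baits = random_lists(rng)
        net = cx.combined_min_degree_network(lists, k=5, ls_min=6.0,
                                             min_degree=2, baits=baits)
        union = nx.Graph()
        for b in baits:
            top = sorted(lists[b].entries, key=lambda kv: (-kv[1], kv[0]))[:5]
            for g, _ in top:
                union.add_edge(b, g)
            for g, ls in lists[b].entries:
                if ls >= 6.0:
                    union.add_edge(b, g)
        pre_deg = dict(union.degree())
        keep_nonbait = {n for n in union if n in set(baits)
                        or pre_deg[n] >= 2}
        oracle = union.subgraph(keep_nonbait).copy()
        oracle.remove_nodes_from(
            [n for n in set(baits) & set(oracle)
             if oracle.degree(n) == 0])
        assert {frozenset(e) for e in net.edges} == \
            {frozenset(e) for e in oracle.edges}
        assert set(net.nodes) == set(oracle.nodes)

    def test_every_retained_coexpressor_had_min_degree(self):
        rng = np.random.default_rng(99)
        lists, baits = random_lists(rng)
        net = cx.combined_min_degree_network(lists, k=5, ls_min=5.0,
                                             min_degree=2, baits=baits)
        topk = cx.top_k_network(lists, 5, baits)
        thr = cx.threshold_network(lists, 5.0, baits)
        union = nx.compose(topk, thr)
        for n in net.nodes:
            if n not in set(baits):
                assert union.degree(n) >= 2

    def test_idempotent_construction(self):
        rng = np.random.default_rng(3)
        lists, baits = random_lists(rng)
        a = cx.combined_min_degree_network(lists, baits=baits)
        b = cx.combined_min_degree_network(lists, baits=baits)
        assert nx.utils.graphs_equal(a, b)


class TestNetworkStats:
    def test_toy_counts_with_bait_bait_double_counting(self):
        net = nx.Graph()
        net.add_edge("CLP1", "G1")
        net.add_edge("TRAP1", "G2")
        net.add_edge("CLP1", "TRAP1")
        stats = cx.network_stats(net, clp_baits=["CLP1"],
                                 trapped_baits=["TRAP1"])
        assert stats.edges_clp == 2 and stats.edges_trapped == 2
        assert stats.n_bait_bait_edges == 1
        assert stats.connectivity == pytest.approx(1.0)

    def test_empty_graph_reports_missing_fractions(self):
        stats = cx.network_stats(nx.Graph())
        assert stats.n_nodes == 0 and np.isnan(stats.connectivity)

    def test_connectivity_identity(self):
        rng = np.random.default_rng(4)
        lists, baits = random_lists(rng)
        net = cx.combined_min_degree_network(lists, baits=baits)
        stats = cx.network_stats(net, clp_baits=baits[:4],
                                 trapped_baits=baits[4:])
        assert stats.connectivity * stats.n_nodes == pytest.approx(
            stats.edges_clp + stats.edges_trapped)
        assert stats.edges_clp + stats.edges_trapped >= stats.n_edges

    def test_counts_match_exhaustive_recount(self):
        rng = np.random.default_rng(10)
        lists, baits = random_lists(rng)
        clp, trapped = baits[:4], baits[4:]
        net = cx.threshold_network(lists, 4.0, baits)
        stats = cx.network_stats(net, clp_baits=clp, trapped_baits=trapped)
        clp_set, trap_set = set(clp), set(trapped)
        assert stats.edges_clp == sum(
            1 for u, v in net.edges if u in clp_set or v in clp_set)
        assert stats.edges_trapped == sum(
            1 for u, v in net.edges if u in trap_set or v in trap_set)


class TestExport:
    def test_sif_for_triangle(self, tmp_path):
        net = nx.Graph()
        for u, v in itertools.combinations(["B1", "B2", "B3"], 2):
            net.add_edge(u, v, rule="topk")
        path = tmp_path / "net.sif"
        cx.export_graph(net, path, fmt="sif")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3 and all("topk" in ln for ln in lines)

    def test_graphml_roundtrip_isomorphic(self, tmp_path):
        rng = np.random.default_rng(6)
        lists, baits = random_lists(rng)
        net = cx.top_k_network(lists, 5, baits)
        path = tmp_path / "net.graphml"
        cx.export_graph(net, path, fmt="graphml")
        back = cx.read_graph(path, fmt="graphml")
        assert nx.is_isomorphic(net, back)
        assert {frozenset(e) for e in net.edges} == \
            {frozenset(e) for e in back.edges}
        u, v = next(iter(net.edges))
        assert back.edges[(u, v)]["ls"] == net.edges[(u, v)]["ls"]

    def test_empty_graph_exports(self, tmp_path):
        path = tmp_path / "empty.graphml"
        cx.export_graph(nx.Graph(), path, fmt="graphml")
        assert cx.read_graph(path).number_of_nodes() == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            cx.export_graph(nx.Graph(), tmp_path / "x", fmt="dot")
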