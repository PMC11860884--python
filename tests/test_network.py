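"""Centralities, hub/core selection and ROC screening vs brute force."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import (
    brute_betweenness,
    brute_harmonic_closeness,
    brute_mcc,
    pair_count_auc,
)
from effimine.network import (
    compute_centralities,
    mcc_scores,
    rank_auc,
    read_network,
    roc_auc_biomarker,
    score_core_genes,
    select_hub_genes,
)


def random_graph(seed, n_max=8, p=0.4):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    graph = nx.Graph()
    graph.add_nodes_from(f"v{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                graph.add_edge(f"v{i}", f"v{j}")
    return graph


class TestCentralities:
    def test_star_center(self):
        star = nx.star_graph(4)
        table = compute_centralities(star)
        assert table.loc[0, "degree"] == 4
        assert table.loc[0, "betweenness"] == 6  # all C(4,2) pairs
        assert table.loc[0, "closeness"] == table["closeness"].max()

    def test_complete_graph_symmetry(self):
        table = compute_centralities(nx.complete_graph(4))
        assert (table["betweenness"] == 0).all()
        assert (table["degree"] == 3).all()

    def test_path_betweenness(self):
        path = nx.path_graph(["a", "b", "c", "d"])
        table = compute_centralities(path)
        assert table.loc["b", "betweenness"] == 2
        assert table.loc["c", "betweenness"] == 2

    def test_isolated_node_contributes_zero_closeness(self):
        graph = nx.Graph()
        graph.add_nodes_from(["a", "b"])
        graph.add_edge("a", "b")
        graph.add_node("c")
        table = compute_centralities(graph)
        assert table.loc["c", "closeness"] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        graph = random_graph(seed)
        table = compute_centralities(graph)
        bc = brute_betweenness(graph)
        cc = brute_harmonic_closeness(graph)
        for v in graph.nodes():
            assert table.loc[v, "degree"] == graph.degree(v)
            assert table.loc[v, "betweenness"] == pytest.approx(bc[v], abs=1e-10)
            assert table.loc[v, "closeness"] == pytest.approx(cc[v], abs=1e-10)

    def test_adding_edge_never_decreases_endpoint_degree(self):
        graph = random_graph(77)
        before = compute_centralities(graph)["degree"]
        nodes = sorted(graph.nodes())
        graph.add_edge(nodes[0], f"v_new")
        after = compute_centralities(graph)["degree"]
        assert after[nodes[0]] >= before[nodes[0]]


class TestHubSelection:
    def test_planted_hub_dominates(self):
        from effimine.synthetic import gen_network

        graph = gen_network(30, planted_hub=0, seed=2)
        table = compute_centralities(graph)
        hubs = select_hub_genes(table, k=5)
        assert "g0" in hubs

    def test_identical_rankings_give_exact_top_k(self):
        # star: every centrality ranks the centre first, then the leaves
        # tied; the symbol tie-break makes all three top lists identical
        table = compute_centralities(nx.star_graph(5))
        hubs = select_hub_genes(table, k=3)
        assert set(hubs) == {0, 1, 2}

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_matches_sort_and_slice_oracle(self, seed):
        graph = random_graph(seed, n_max=20)
        table = compute_centralities(graph)
        k = 6
        expected = None
        for col in ("degree", "closeness", "betweenness"):
            ranked = sorted(
                table[col].items(), key=lambda kv: (-kv[1], str(kv[0]))
            )
            top = {label for label, _ in ranked[:k]}
            expected = top if expected is None else expected & top
        assert set(select_hub_genes(table, k=k)) == expected

    def test_small_graph_warns_and_uses_all_nodes(self, caplog):
        table = compute_centralities(nx.path_graph(3))
        with caplog.at_level("WARNING"):
            hubs = select_hub_genes(table, k=10)
        assert set(hubs) == {0, 1, 2}


class TestCliqueScore:
    def test_triangle(self):
        scores = mcc_scores(nx.complete_graph(3))
        assert all(v == 2 for v in scores.values())

    def test_triangle_with_pendant(self):
        graph = nx.complete_graph(["a", "b", "c"])
        graph.add_edge("c", "d")
        scores = mcc_scores(graph)
        assert scores["d"] == 1
        assert scores["c"] == 3  # (3−1)! + (2−1)!
        assert scores["a"] == 2

    def test_edgeless_nodes_score_one(self):
        graph = nx.empty_graph(3)
        assert set(mcc_scores(graph).values()) == {1}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_subset_grown_enumeration(self, seed):
        graph = random_graph(seed + 500, n_max=10)
        assert mcc_scores(graph) == brute_mcc(graph)

    def test_core_ranking_deterministic_tie_break(self):
        graph = nx.complete_graph(["b", "a", "c"])
        assert score_core_genes(graph, top=2) == ["a", "b"]

    def test_clique_budget_aborts(self):
        graph = nx.complete_multipartite_graph(3, 3, 3)
        with pytest.raises(RuntimeError, match="budget"):
            mcc_scores(graph, clique_budget=2)


class TestAUC:
    def test_perfect_separation(self):
        assert rank_auc([5, 6, 7], [1, 2, 3]) == 1.0

    def test_all_ties_give_half(self):
        assert rank_auc([4.0, 4.0], [4.0, 4.0]) == 0.5

    def test_three_vs_three_worked_example(self):
        """Exhaustive pair counting: 6 concordant + 2 ties over 9 pairs."""
        case, control = [5, 6, 7], [4, 5, 6]
        oracle = pair_count_auc(case, control)
        assert oracle == pytest.approx(7 / 9)
        assert rank_auc(case, control) == pytest.approx(oracle, abs=1e-12)

    def test_inverted_marker_reported_below_half(self):
        assert rank_auc([1, 2], [5, 6]) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_mann_whitney_u_and_sklearn(self, seed):
        from scipy import stats
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        case = rng.normal(1, 1, size=8)
        control = rng.normal(0, 1, size=11)
        auc = rank_auc(case, control)
        u = stats.mannwhitneyu(case, control, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (8 * 11), abs=1e-12)
        labels = [1] * 8 + [0] * 11
        assert auc == pytest.approx(
            roc_auc_score(labels, np.concatenate([case, control])), abs=1e-12
        )
        assert auc == pytest.approx(pair_count_auc(case, control), abs=1e-12)

    def test_biomarker_screen_flags_and_skips(self, caplog):
        matrix = pd.DataFrame(
            {"c0": [10, 1], "c1": [11, 2], "n0": [1, 1.5], "n1": [2, 2.5]},
            index=["sep", "mid"],
        )
        groups = pd.Series(
            ["case", "case", "control", "control"],
            index=["c0", "c1", "n0", "n1"],
        )
        with caplog.at_level("WARNING"):
            screen = roc_auc_biomarker(matrix, groups, ["sep", "mid", "absent"])
        assert list(screen["gene"]) == ["sep", "mid"]
        assert screen.set_index("gene").loc["sep", "auc"] == 1.0
        assert bool(screen.set_index("gene").loc["sep", "candidate"])


def test_read_network_edge_list_and_sif(tmp_path):
    edges = tmp_path / "edges.tsv"
    edges.write_text("a\tb\nb\tc\n")
    graph = read_network(edges)
    assert set(graph.edges()) == {("a", "b"), ("b", "c")}
    sif = tmp_path / "net.sif"
    sif.write_text("a pp b c\nd pp d\n")
    graph = read_network(sif)
    assert set(map(frozenset, graph.edges())) == {
        frozenset({"a", "b"}), frozenset({"a", "c"})
    }
    assert nx.number_of_selfloops(graph) == 0
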