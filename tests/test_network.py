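"""Network statistics: class-edge counts, permutation and rewiring nulls,
coexpression construction and the sweep chi-square."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wgtevol.network_tests import (
    both_triplicated, build_coexpression, count_class_edges,
    label_permutation_test, metabolic_edge_stat, rewire_test,
    same_subgenome_single_copy, subgenome_pair, sweep_association,
)
from wgtevol.synthetic_data import simulate_labeled_network


def _net(nodes, edges):
    g = nx.Graph()
    for n, attrs in nodes.items():
        g.add_node(n, **attrs)
    g.add_edges_from(edges)
    return g


class TestCountClassEdges:
    def test_complete_graph_same_label(self):
        nodes = {i: {"subgenome": "LF", "copy_status": "single"} for i in range(4)}
        g = _net(nodes, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert count_class_edges(g, same_subgenome_single_copy)["LF"] == 6

    def test_bipartite_labels_no_same_label_edges(self):
        nodes = {i: {"subgenome": "LF" if i < 3 else "MF1", "copy_status": "single"}
                 for i in range(6)}
        g = _net(nodes, [(i, j) for i in range(3) for j in range(3, 6)])
        counts = count_class_edges(g, same_subgenome_single_copy)
        assert sum(counts.values()) == 0

    def test_hand_built_mixed_network(self):
        nodes = {
            0: {"subgenome": "LF", "copy_status": "single"},
            1: {"subgenome": "LF", "copy_status": "single"},
            2: {"subgenome": "LF", "copy_status": "triplicated"},
            3: {"subgenome": "MF1", "copy_status": "single"},
            4: {"subgenome": "MF1", "copy_status": "single"},
            5: {"subgenome": "MF2", "copy_status": "triplicated"},
            6: {"subgenome": "unassigned", "copy_status": "single"},
            7: {"subgenome": "MF2", "copy_status": "single"},
        }
        edges = [(0, 1), (0, 2), (3, 4), (2, 5), (6, 0), (7, 5), (1, 3)]
        single = count_class_edges(_net(nodes, edges), same_subgenome_single_copy)
        assert single == {"LF": 1, "MF1": 1}
        trip = count_class_edges(_net(nodes, edges), both_triplicated)
        assert trip == {"triplet": 1}


class TestPermutationTest:
    def test_label_invariant_statistic_gives_p_one(self):
        g = simulate_labeled_network(n_nodes=40, degree_param=4, seed=0)
        res = label_permutation_test(g, lambda h: h.number_of_edges(),
                                     n_perm=50, seed=1)
        assert res.p_upper == pytest.approx(1.0) or res.p_lower == pytest.approx(1.0)
        assert res.null_sd == 0.0

    def test_planted_extreme_network_hits_smallest_p(self):
        # an LF clique plus isolated MF1 nodes: only 1 of the ~1.8e5 label
        # permutations reproduces the observed same-label count
        nodes = {}
        edges = []
        for i in range(10):
            nodes[i] = {"subgenome": "LF", "copy_status": "single"}
            nodes[10 + i] = {"subgenome": "MF1", "copy_status": "single"}
        for i in range(10):
            for j in range(i + 1, 10):
                edges.append((i, j))
        g = _net(nodes, edges)

        def stat(h):
            return sum(count_class_edges(h, same_subgenome_single_copy).values())

        res = label_permutation_test(g, stat, n_perm=999, seed=0)
        assert res.p_upper == pytest.approx(1 / 1000)

    def test_fixed_seed_reproducible(self):
        g = simulate_labeled_network(n_nodes=30, degree_param=4, seed=3)

        def stat(h):
            return sum(count_class_edges(h, same_subgenome_single_copy).values())

        a = label_permutation_test(g, stat, n_perm=99, seed=11)
        b = label_permutation_test(g, stat, n_perm=99, seed=11)
        assert a.p_upper == b.p_upper and a.p_lower == b.p_lower

    def test_all_nodes_frozen_rejected(self):
        g = simulate_labeled_network(n_nodes=10, degree_param=3, seed=0)
        with pytest.raises(ValueError):
            label_permutation_test(g, lambda h: 0.0, n_perm=10,
                                   frozen_nodes=list(g.nodes()))


class TestMetabolicEdges:
    def test_no_single_copy_genes_no_counts(self):
        rnet = nx.path_graph(3)
        genes = {0: ["g0"], 1: ["g1"], 2: ["g2"]}
        labels = {g: ("LF", "triplicated") for g in ("g0", "g1", "g2")}
        counts = metabolic_edge_stat(rnet, genes, labels)
        assert sum(counts.values()) == 0

    def test_single_shared_metabolite_pair(self):
        rnet = nx.Graph([(0, 1)])
        genes = {0: ["gA"], 1: ["gB"]}
        labels = {"gA": ("LF", "single"), "gB": ("LF", "single")}
        assert metabolic_edge_stat(rnet, genes, labels)["LF"] == 1

    def test_same_gene_on_both_reactions_is_not_a_pair(self):
        rnet = nx.Graph([(0, 1)])
        genes = {0: ["gA"], 1: ["gA"]}
        labels = {"gA": ("LF", "single")}
        assert metabolic_edge_stat(rnet, genes, labels)["LF"] == 0

    def test_toy_pathway_matches_hand_count(self):
        rnet = nx.path_graph(6)
        genes = {i: [f"g{i}"] for i in range(6)}
        labels = {
            "g0": ("LF", "single"), "g1": ("LF", "single"),   # edge 0-1: LF
            "g2": ("MF1", "single"), "g3": ("MF1", "single"),  # edge 2-3: MF1
            "g4": ("MF2", "triplicated"), "g5": ("MF2", "single"),
        }
        counts = metabolic_edge_stat(rnet, genes, labels)
        assert counts == {"LF": 1, "MF1": 1, "MF2": 0}


class TestCoexpression:
    def test_perfectly_concordant_and_reversed_ranks_both_edge(self):
        base = np.arange(10, dtype=float)
        expr = pd.DataFrame({"c%d" % j: [base[j], base[j] * 2 + 1, 9 - base[j]]
                             for j in range(10)}, index=["g1", "g2", "g3"])
        net = build_coexpression(expr, threshold=0.9)
        assert net.has_edge("g1", "g2")      # rho = +1
        assert net.has_edge("g1", "g3")      # rho = -1 (negative rule)

    def test_gene_missing_too_many_conditions_excluded(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(3, 32)),
                            index=["ok0", "ok1", "bad"],
                            columns=[f"lib{j}" for j in range(32)])
        expr.iloc[2, :2] = np.nan  # two missing values > max_missing=1
        expr.iloc[1, 0] = np.nan   # one missing value: allowed
        net = build_coexpression(expr, max_missing=1)
        assert "bad" not in net and "ok1" in net

    def test_constant_gene_skipped_with_warning(self):
        expr = pd.DataFrame({"c%d" % j: [1.0, float(j)] for j in range(8)},
                            index=["flat", "varies"])
        with pytest.warns(RuntimeWarning):
            net = build_coexpression(expr)
        assert "flat" not in net

    def test_independent_noise_produces_no_edges(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(30, 32)))
        net = build_coexpression(expr, threshold=0.9)
        assert net.number_of_edges() == 0

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(12, 20)),
                            index=[f"g{i}" for i in range(12)])
        expr.iloc[0] = expr.iloc[1] * 3 + 1  # plant one edge
        a = build_coexpression(expr, threshold=0.9)
        b = build_coexpression(expr.iloc[::-1], threshold=0.9)
        assert set(map(frozenset, a.edges())) == set(map(frozenset, b.edges()))


class TestRewire:
    def test_degree_sequence_preserved_exactly(self):
        g = simulate_labeled_network(n_nodes=60, degree_param=5, seed=4)
        res = rewire_test(g, n_rewire=5, seed=0)
        assert res.null_counts.shape[0] == 5
        # degree preservation is asserted inside networkx; spot-check by
        # re-running the same swap sequence
        h = g.copy()
        rng = np.random.default_rng(0)
        nx.double_edge_swap(h, nswap=5 * g.number_of_edges(),
                            max_tries=100 * g.number_of_edges(),
                            seed=int(rng.integers(2 ** 31)))
        assert dict(h.degree()) == dict(g.degree())
        assert nx.number_of_selfloops(h) == 0

    def test_star_graph_unchanged_p_one(self):
        g = nx.star_graph(5)
        for n in g.nodes():
            g.nodes[n]["subgenome"] = "LF"
        res = rewire_test(g, n_rewire=20, seed=0)
        assert all(p == pytest.approx(1.0) for p in res.p_upper.values())

    def test_planted_same_class_excess_detected(self):
        g = simulate_labeled_network(n_nodes=150, degree_param=6,
                                     enrichment=10.0, seed=5)
        res = rewire_test(g, n_rewire=100, seed=1)
        for cls in ("LF", "MF1", "MF2"):
            assert res.p_upper[(cls, cls)] < 0.05

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError):
            rewire_test(nx.Graph([(0, 1)]), n_rewire=5)


class TestSweepAssociation:
    def test_proportional_table_gives_zero(self):
        genes = pd.DataFrame({
            "subgenome": ["LF"] * 40 + ["MF1"] * 20 + ["MF2"] * 20,
            "sweep": [1] * 10 + [0] * 30 + [1] * 5 + [0] * 15 + [1] * 5 + [0] * 15,
        })
        res = sweep_association(genes)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_hand_formula(self):
        genes = pd.DataFrame({
            "subgenome": ["LF"] * 30 + ["MF1"] * 30,
            "sweep": [1] * 10 + [0] * 20 + [1] * 20 + [0] * 10,
        })
        res = sweep_association(genes)
        table = np.array([[10, 20], [20, 10]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(hand)
        assert res.df == 1

    def test_three_by_two_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        genes = pd.DataFrame({
            "subgenome": rng.choice(["LF", "MF1", "MF2"], size=120),
            "sweep": rng.integers(0, 2, size=120)})
        assert sweep_association(genes).df == 2

    def test_empty_category_rejected(self):
        genes = pd.DataFrame({"subgenome": ["LF", "LF"], "sweep": [1, 1]})
        with pytest.raises(ValueError):
            sweep_association(genes)
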