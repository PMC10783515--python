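import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from muxtalk.benchmark import (
    BenchmarkLabels,
    chi_rank,
    direct_edge_rank,
    edge_overlap_rank,
    evaluate,
    node_overlap_rank,
    path_count_statistic,
    precision_at_rank,
    yen_k_shortest,
)
from muxtalk.randomize import build_ensemble
from muxtalk.synthgen import gen_labels

from oracles import (
    brute_force_simple_paths,
    mann_whitney_auroc,
    two_sided_hypergeom_p,
)


class TestNodeOverlap:
    def test_identical_sets_most_significant(self):
        membership = {
            "A": set("abcdefgh"), "B": set("abcdefgh"), "C": set("xy"),
        }
        universe = set("abcdefghxy") | {f"u{i}" for i in range(30)}
        table = node_overlap_rank(membership, universe)
        top = table.iloc[0]
        assert {top.pathway_a, top.pathway_b} == {"A", "B"}

    def test_p_matches_hypergeometric_oracle(self):
        # |A|=10, |B|=8, overlap 6, universe 40
        a = {f"s{i}" for i in range(6)} | {f"a{i}" for i in range(4)}
        b = {f"s{i}" for i in range(6)} | {f"b{i}" for i in range(2)}
        universe = a | b | {f"u{i}" for i in range(40 - len(a | b))}
        assert len(universe) == 40
        table = node_overlap_rank({"A": a, "B": b}, universe)
        expected = two_sided_hypergeom_p(6, 10, 8, 40)
        assert table["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_undetected(self):
        table = node_overlap_rank({"A": {"1"}, "B": {"2"}}, {"1", "2", "3"})
        assert not table["detected"].any()

    def test_bh_fdr_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        membership = {
            f"P{k}": {f"g{i}" for i in rng.choice(60, size=12, replace=False)}
            for k in range(6)
        }
        universe = {f"g{i}" for i in range(60)}
        table = node_overlap_rank(membership, universe)
        unordered = table.drop_duplicates(subset=["p", "fdr"]).sort_values("p")
        assert (unordered["fdr"].diff().dropna() >= -1e-12).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            node_overlap_rank({"A": set(), "B": set()}, set())

    def test_symmetric_values_for_both_orderings(self):
        membership = {"A": set("abc"), "B": set("bcd"), "C": set("xyz")}
        table = node_overlap_rank(membership)
        ab = table[(table.pathway_a == "A") & (table.pathway_b == "B")]["p"].iloc[0]
        ba = table[(table.pathway_a == "B") & (table.pathway_b == "A")]["p"].iloc[0]
        assert ab == ba


class TestEdgeOverlap:
    def test_identical_edge_sets_most_significant(self):
        e = {("a", "b"), ("b", "c"), ("c", "d")}
        table = edge_overlap_rank(
            {"A": e, "B": set(e), "C": {("x", "y")}},
            universe_genes=list("abcdxy"),
        )
        top = table.iloc[0]
        assert {top.pathway_a, top.pathway_b} == {"A", "B"}

    def test_p_matches_hypergeometric_oracle(self):
        # 3-vs-3 edges sharing 2 over N=6 genes -> 30 ordered positions
        a = {("a", "b"), ("b", "c"), ("c", "d")}
        b = {("a", "b"), ("b", "c"), ("d", "e")}
        table = edge_overlap_rank({"A": a, "B": b}, universe_genes=list("abcdef"))
        expected = two_sided_hypergeom_p(2, 3, 3, 30)
        assert table["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_shared_edges_undetected(self):
        table = edge_overlap_rank(
            {"A": {("a", "b")}, "B": {("c", "d")}}, universe_genes=list("abcd")
        )
        assert not table["detected"].any()


class TestDirectEdges:
    def test_planted_dense_pair_ranks_first(self, net_factory):
        rng = np.random.default_rng(5)
        sig = [("a1", "a2", "activation", True, "A"),
               ("b1", "b2", "activation", True, "B"),
               ("c1", "c2", "activation", True, "C")]
        # dense direct edges between A and B, sparse random background so the
        # rewiring null can redistribute edges
        ppi = [(f"a{i}", f"b{j}") for i in (1, 2) for j in (1, 2)]
        background = [f"u{i}" for i in range(30)]
        for _ in range(40):
            u, v = rng.choice(30, size=2, replace=False)
            ppi.append((background[u], background[v]))
        net = net_factory(sig, [("a1", "b1")], ppi_edges=ppi)
        membership = {"A": {"a1", "a2"}, "B": {"b1", "b2"}, "C": {"c1", "c2"}}
        ens = build_ensemble(net, 30, q=5, master_seed=0)
        table = direct_edge_rank(net, ens, membership, n_rand=30)
        top = table.iloc[0]
        assert {top.pathway_a, top.pathway_b} == {"A", "B"}
        assert top.z > 0

    def test_empty_exclusive_sets_undetected(self, net_factory):
        net = net_factory([("a", "b", "activation", True)], [("a", "b")])
        membership = {"A": {"a", "b"}, "B": {"a", "b"}}
        ens = build_ensemble(net, 5, q=2, master_seed=0)
        table = direct_edge_rank(net, ens, membership, n_rand=5)
        assert not table["detected"].any()


class TestYen:
    def test_two_parallel_length_two_paths(self):
        g = nx.DiGraph([("a", "b"), ("b", "d"), ("a", "c"), ("c", "d")])
        paths = yen_k_shortest(g, "a", "d", 2)
        assert paths == [["a", "b", "d"], ["a", "c", "d"]]

    def test_unique_path_on_chain(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        assert yen_k_shortest(g, "a", "c", 1) == [["a", "b", "c"]]

    def test_disconnected_returns_empty(self):
        g = nx.DiGraph()
        g.add_edge("a", "b")
        g.add_node("z")
        assert yen_k_shortest(g, "a", "z", 3) == []

    def test_absent_node_rejected(self):
        g = nx.DiGraph([("a", "b")])
        with pytest.raises(KeyError):
            yen_k_shortest(g, "a", "missing", 1)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_enumeration(self, seed):
        """Yen's K shortest paths equal brute-force DFS enumeration on all
        random digraphs with at most 8 nodes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        edges = {
            (int(i), int(j))
            for i, j in rng.integers(0, n, size=(int(rng.integers(4, 18)), 2))
            if i != j
        }
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        k = int(rng.integers(1, 6))
        got = yen_k_shortest(g, 0, n - 1, k)
        expected = brute_force_simple_paths(edges, 0, n - 1, k)
        assert got == expected


class TestChi:
    def base_net(self, net_factory):
        sig = [("r1", "m", "activation", True, "A"), ("m", "t1", "activation", True, "A"),
               ("r2", "m2", "activation", True, "B"), ("m2", "t2", "activation", True, "B")]
        ppi = [("m", "t2"), ("m2", "t1")]
        net = net_factory(sig, [("r1", "t2")], ppi_edges=ppi)
        membership = {"A": {"r1", "m", "t1"}, "B": {"r2", "m2", "t2"}}
        return net, membership

    def test_chi_fn_required(self, net_factory):
        net, membership = self.base_net(net_factory)
        with pytest.raises(ValueError, match="chi_fn"):
            chi_rank(net, {"r1"}, {"t2"}, membership, chi_fn=None)

    def test_missing_receptors_undetected(self, net_factory):
        net, membership = self.base_net(net_factory)
        table = chi_rank(net, set(), {"t1", "t2"}, membership, k=2,
                         chi_fn=path_count_statistic)
        assert not table["detected"].any()

    def test_path_count_statistic_plugin(self, net_factory):
        net, membership = self.base_net(net_factory)
        table = chi_rank(net, {"r1", "r2"}, {"t1", "t2"}, membership, k=2,
                         chi_fn=path_count_statistic)
        ab = table[(table.pathway_a == "A") & (table.pathway_b == "B")]
        assert ab["detected"].iloc[0]
        assert ab["chi"].iloc[0] >= 1

    def test_reproducible_with_ensemble(self, net_factory):
        net, membership = self.base_net(net_factory)
        ens = build_ensemble(net, 10, q=3, master_seed=4)
        t1 = chi_rank(net, {"r1"}, {"t2"}, membership, k=2,
                      chi_fn=path_count_statistic, ensemble=ens, n_rand=10)
        t2 = chi_rank(net, {"r1"}, {"t2"}, membership, k=2,
                      chi_fn=path_count_statistic, ensemble=ens, n_rand=10)
        pd.testing.assert_frame_equal(t1, t2)


def ranked_frame(order, detected=None):
    rows = []
    for rank, pair in enumerate(order, start=1):
        det = True if detected is None else detected[pair]
        rows.append({"pathway_a": pair[0], "pathway_b": pair[1],
                     "rank": rank if det else None, "detected": det})
    return pd.DataFrame(rows)


class TestEvaluate:
    def test_perfect_ranking_auroc_one(self):
        labels = gen_labels(["a", "b", "c"], [("a", "b"), ("a", "c")])
        order = [("a", "b"), ("a", "c"), ("b", "a"), ("b", "c"), ("c", "a"), ("c", "b")]
        ev = evaluate(ranked_frame(order), labels, "deterministic")
        assert ev.auroc == 1.0

    def test_alternating_ranking_auroc(self):
        labels = BenchmarkLabels(
            labels={("p", "1"): 1, ("n", "1"): 0, ("p", "2"): 1, ("n", "2"): 0},
            universe=[("p", "1"), ("n", "1"), ("p", "2"), ("n", "2")],
        )
        order = [("p", "1"), ("n", "1"), ("p", "2"), ("n", "2")]
        ev = evaluate(ranked_frame(order), labels, "deterministic")
        # oracle: 3 of 4 positive-negative pairs concordant
        assert ev.auroc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(20))
    def test_auroc_equals_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        pairs = [(f"x{i}", "y") for i in range(n)]
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        labels = BenchmarkLabels(
            labels={p: int(v) for p, v in zip(pairs, y)}, universe=pairs
        )
        order = list(pairs)
        rng.shuffle(order)
        ev = evaluate(ranked_frame(order), labels, "deterministic")
        expected = mann_whitney_auroc(order, labels.labels)
        assert ev.auroc == pytest.approx(expected, abs=1e-12)

    def test_stochastic_reduces_to_deterministic_without_undetected(self):
        labels = gen_labels(["a", "b", "c"], [("a", "b")])
        order = labels.universe
        det = evaluate(ranked_frame(order), labels, "deterministic")
        sto = evaluate(ranked_frame(order), labels, "stochastic", n_shuffles=25, seed=3)
        assert sto.auroc == pytest.approx(det.auroc)
        assert sto.auroc_sd == 0.0 and sto.auprc_sd == 0.0

    def test_all_undetected_is_coin_flip(self):
        labels = gen_labels([f"p{i}" for i in range(5)], [("p0", "p1"), ("p1", "p2")])
        frame = ranked_frame(labels.universe, detected={p: False for p in labels.universe})
        ev = evaluate(frame, labels, "stochastic", n_shuffles=300, seed=0)
        assert abs(ev.auroc - 0.5) <= 3 * max(ev.auroc_sd / math.sqrt(300), 0.01)

    def test_single_class_rejected(self):
        labels = BenchmarkLabels(labels={("a", "b"): 1}, universe=[("a", "b")])
        with pytest.raises(ValueError):
            evaluate(ranked_frame([("a", "b")]), labels, "deterministic")


class TestPrecisionAtRank:
    def test_mixed_prefix(self):
        ranked = ["p1", "p2", "n1", "p3"]
        out = precision_at_rank(ranked, {"p1", "p2", "p3"}, 4)
        assert out == [1.0, 1.0, 2 / 3, 3 / 4]

    def test_no_positives_in_top(self):
        assert precision_at_rank(["n1", "n2"], {"p"}, 2) == [0.0, 0.0]

    def test_all_positive(self):
        assert precision_at_rank(["p1", "p2"], {"p1", "p2"}, 2) == [1.0, 1.0]


class TestLabels:
    def test_600_ordered_pairs_for_25_pathways(self):
        labels = gen_labels([f"p{i}" for i in range(25)], [])
        assert len(labels.universe) == 600

    def test_3540_ordered_pairs_for_60_pathways(self):
        labels = gen_labels([f"p{i}" for i in range(60)], [])
        assert len(labels.universe) == 3540

    def test_small_universe_split(self):
        labels = gen_labels(["a", "b", "c"], [("a", "b")])
        assert len(labels.universe) == 6
        assert len(labels.positives) == 1
        assert len(labels.negatives) == 5

    def test_duplicate_positives_rejected(self):
        with pytest.raises(ValueError):
            gen_labels(["a", "b"], [("a", "b"), ("a", "b")])
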