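import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from muxtalk.multilinks import (
    N_MULTILINK_TYPES,
    all_multilink_types,
    count_multilinks,
    count_zero_signaling,
    decode_multilink,
    encode_multilink,
    multilink_stats,
    profile_subset,
)
from muxtalk.netbuild import LayerMatrix

from oracles import brute_force_multilink_counts, brute_force_zero_counts


def layer(n, arcs=(), und=(), label="sig"):
    return LayerMatrix.from_edges(label, n, arcs=arcs, undirected_pairs=und)


class TestEncoding:
    def test_roundtrip_and_injectivity(self):
        codes = {encode_multilink(s, r) for s, r in all_multilink_types()}
        assert len(codes) == N_MULTILINK_TYPES
        for s, r in all_multilink_types():
            assert decode_multilink(encode_multilink(s, r)) == (s, r)

    @pytest.mark.parametrize("s,r", [(12, 0), (-1, 0), (3, 2), (3, -2)])
    def test_out_of_range_rejected(self, s, r):
        with pytest.raises(ValueError):
            encode_multilink(s, r)

    def test_decode_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decode_multilink(36)


class TestCountMultilinks:
    def test_aligned_directed_pair(self):
        counts = count_multilinks(layer(3, arcs=[(0, 1)]), layer(3, arcs=[(0, 1)], label="GRN"), 1)
        assert counts == {(1, 1): 1, (1, -1): 0, (1, 0): 0}

    def test_opposed_directed_pair(self):
        counts = count_multilinks(layer(3, arcs=[(0, 1)]), layer(3, arcs=[(1, 0)], label="GRN"), 1)
        assert counts == {(1, 1): 0, (1, -1): 1, (1, 0): 0}

    def test_undirected_sig_with_grn_counts_both_signs(self):
        counts = count_multilinks(layer(3, und=[(0, 1)]), layer(3, arcs=[(0, 1)], label="GRN"), 2)
        assert counts[(2, 1)] == 1 and counts[(2, -1)] == 1

    def test_undirected_sig_alone_not_double_counted(self):
        counts = count_multilinks(layer(3, und=[(0, 1)]), layer(3, arcs=[(1, 2)], label="GRN"), 2)
        assert counts[(2, 0)] == 1

    def test_restrict_pairs_confines_counting(self):
        sig = layer(4, arcs=[(0, 1), (2, 3)])
        grn = layer(4, arcs=[(0, 1), (2, 3)], label="GRN")
        counts = count_multilinks(sig, grn, 1, restrict_pairs={(0, 1), (1, 0)})
        assert counts[(1, 1)] == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_multilinks(layer(3), layer(4, label="GRN"), 1)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        """Edge-set counting equals a dense O(N^2) scan on random toys."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        arcs, und = set(), set()
        for _ in range(int(rng.integers(2, 14))):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            pair = (min(i, j), max(i, j))
            if pair in und or (i, j) in arcs or (j, i) in arcs:
                continue
            if rng.random() < 0.4:
                und.add(pair)
            else:
                arcs.add((int(i), int(j)))
        g_arcs, g_und = set(), set()
        for _ in range(int(rng.integers(1, 10))):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            pair = (min(i, j), max(i, j))
            if pair in g_und or (i, j) in g_arcs:
                continue
            if (j, i) in g_arcs:
                g_arcs.discard((j, i))
                g_und.add(pair)
            elif rng.random() < 0.2:
                g_und.add(pair)
            else:
                g_arcs.add((int(i), int(j)))
        sig = LayerMatrix("sig", n, arcs, und)
        grn = LayerMatrix("GRN", n, g_arcs, g_und)
        expected = brute_force_multilink_counts(
            sig.matrix.toarray(), grn.matrix.toarray(), 5
        )
        assert count_multilinks(sig, grn, 5) == expected
        expected0 = brute_force_zero_counts(sig.matrix.toarray(), grn.matrix.toarray())
        assert count_zero_signaling(sig, grn) == expected0

    def test_undirected_symmetry_invariant(self):
        """(S,+1) == (S,-1) exactly for layers of only undirected edges."""
        rng = np.random.default_rng(7)
        n = 10
        und = {(int(a), int(b)) for a, b in
               ((min(i, j), max(i, j)) for i, j in rng.integers(0, n, size=(15, 2)) if i != j)}
        grn_arcs = {(int(i), int(j)) for i, j in rng.integers(0, n, size=(12, 2)) if i != j}
        grn_arcs = {a for a in grn_arcs if (a[1], a[0]) not in grn_arcs}
        sig = LayerMatrix("sig", n, set(), und)
        grn = LayerMatrix("GRN", n, grn_arcs, set())
        counts = count_multilinks(sig, grn, 2)
        assert counts[(2, 1)] == counts[(2, -1)]

    def test_conservation_total_counts_equal_edges(self):
        rng = np.random.default_rng(3)
        n = 12
        arcs = {(int(i), int(j)) for i, j in rng.integers(0, n, size=(10, 2)) if i != j}
        arcs = {a for a in arcs if (a[1], a[0]) not in arcs}
        sig = LayerMatrix("sig", n, arcs, {(0, 1), (2, 3)} - {tuple(sorted(a)) for a in arcs})
        grn_arcs = {(int(i), int(j)) for i, j in rng.integers(0, n, size=(8, 2)) if i != j}
        grn = LayerMatrix("GRN", n, {a for a in grn_arcs if (a[1], a[0]) not in grn_arcs}, set())
        counts = count_multilinks(sig, grn, 4)
        # conservation: each signaling edge lands in exactly one R bucket,
        # except directed edges with regulatory arcs in both directions and
        # undirected edges with any regulatory overlap, which land in two
        extra = 0
        for i, j in sig.directed:
            f = (i, j) in grn.directed or (min(i, j), max(i, j)) in grn.undirected
            b = (j, i) in grn.directed or (min(i, j), max(i, j)) in grn.undirected
            if f and b:
                extra += 1
        for i, j in sig.undirected:
            if ((i, j) in grn.directed or (j, i) in grn.directed
                    or (i, j) in grn.undirected):
                extra += 1
        assert sum(counts.values()) == sig.n_edges + extra


class TestZeroSignaling:
    def test_lone_grn_edge(self):
        counts = count_zero_signaling(layer(3, label="KEGGPPI"), layer(3, arcs=[(0, 1)], label="GRN"))
        assert counts[(0, 1)] == 1

    def test_occupied_position_excluded(self):
        counts = count_zero_signaling(
            layer(3, und=[(0, 1)], label="KEGGPPI"), layer(3, arcs=[(0, 1)], label="GRN")
        )
        assert counts[(0, 1)] == 0

    def test_mixed_toy(self):
        # N=4, two GRN-only arcs, one KEGGPPI-only undirected edge
        kegg = layer(4, und=[(2, 3)], label="KEGGPPI")
        grn = layer(4, arcs=[(0, 1), (1, 2)], label="GRN")
        counts = count_zero_signaling(kegg, grn)
        assert counts[(0, 1)] == 2

    def test_zero_zero_is_arithmetic_complement(self):
        kegg = layer(5, und=[(0, 1)], arcs=[(2, 3)], label="KEGGPPI")
        grn = layer(5, arcs=[(0, 4)], label="GRN")
        counts = count_zero_signaling(kegg, grn)
        occupied_pairs = 3
        assert counts[(0, 0)] == 5 * 4 - 2 * occupied_pairs


class TestMultilinkStats:
    def test_z_formula(self):
        rng = np.random.default_rng(0)
        c_r = rng.normal(10, 4, size=100)
        c_r = (c_r - c_r.mean()) / c_r.std() * 4 + 10  # exact mean 10, sd 4
        st_ = multilink_stats(20, c_r, 100)
        assert st_.z == pytest.approx(2.5, abs=1e-12)

    def test_p_is_tail_fraction(self):
        c_r = [5.0] * 97 + [10.0, 11.0, 12.0]  # mean < 10, exactly 3 values >= 10
        st_ = multilink_stats(10, c_r, 100)
        assert st_.z > 0
        assert st_.p_emp == pytest.approx(0.03)

    def test_lower_tail_when_z_negative(self):
        c_r = [10.0] * 97 + [1.0, 2.0, 2.0]
        st_ = multilink_stats(2, c_r, 100)
        assert st_.z < 0
        assert st_.p_emp == pytest.approx(0.03)

    def test_degenerate_null_all_equal(self):
        st_ = multilink_stats(5, [5.0] * 20, 20)
        assert st_.sigma_zero
        assert math.isnan(st_.z)
        assert st_.p_emp == 1.0

    def test_degenerate_null_with_excess(self):
        st_ = multilink_stats(7, [5.0] * 20, 20)
        assert st_.sigma_zero and st_.z == math.inf and st_.p_emp == 0.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            multilink_stats(1, [], 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(0, 50), min_size=5, max_size=40),
        st.integers(0, 60),
        st.integers(2, 9),
    )
    def test_scale_invariance_of_z(self, c_r, c_a, factor):
        """Multiplying all counts by a constant leaves z unchanged."""
        base = multilink_stats(c_a, c_r, len(c_r))
        scaled = multilink_stats(c_a * factor, [c * factor for c in c_r], len(c_r))
        if math.isnan(base.z):
            assert math.isnan(scaled.z)
        else:
            assert scaled.z == pytest.approx(base.z, rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 30), min_size=5, max_size=30), st.integers(0, 40))
    def test_p_monotone_in_actual_count(self, c_r, c_a):
        """With a fixed null, increasing c_a never increases the upper-tail p."""
        first = multilink_stats(c_a, c_r, len(c_r))
        second = multilink_stats(c_a + 1, c_r, len(c_r))
        if first.z > 0 and second.z > 0:
            assert second.p_emp <= first.p_emp


class TestProfileSubset:
    def test_whole_network_zero_overlap_toy(self, net_factory):
        from muxtalk.randomize import build_ensemble

        # GRN disjoint from signaling by construction
        net = net_factory(
            [("A", "B", "activation", True), ("C", "D", "activation", True)],
            [("E", "F"), ("F", "G")],
            extra_nodes=["E", "F", "G"],
        )
        ens = build_ensemble(net, 5, q=2, master_seed=0)
        prof = profile_subset(net, ens, "whole-network", None, 5)
        assert prof.counts[(0, 1)] == 2  # every GRN edge is signaling-free
        assert prof.counts[(1, 1)] == 0

    def test_single_position_ppi_grn(self, net_factory):
        from muxtalk.randomize import build_ensemble

        net = net_factory(
            [("A", "B", "activation", True)], [("C", "D")], ppi_edges=[("C", "D")]
        )
        c, d = net.gene_index["C"], net.gene_index["D"]
        ens = build_ensemble(net, 4, q=2, master_seed=1)
        prof = profile_subset(net, ens, "one-pos", {(c, d), (d, c)}, 4)
        assert prof.counts[(9, 1)] == 1
        assert prof.counts[(9, -1)] == 1  # undirected ppi edge: both signs
        # the ppi edge is carried by every typed layer, so each S layer sees it
        for s in range(1, 12):
            assert prof.counts[(s, 1)] == 1 and prof.counts[(s, -1)] == 1
        assert prof.counts[(0, 1)] == 0  # position occupied on KEGGPPI

    def test_null_counts_have_requested_length(self, net_factory):
        from muxtalk.randomize import build_ensemble

        net = net_factory([("A", "B", "activation", True)], [("A", "B")])
        ens = build_ensemble(net, 6, q=2, master_seed=2)
        prof = profile_subset(net, ens, "x", None, 6)
        assert all(len(v) == 6 for v in prof.null_counts.values())
        frame = prof.to_frame()
        assert set(frame.columns) >= {"S", "R", "count", "z", "p_emp", "significant"}
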