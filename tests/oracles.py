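"""Independent brute-force oracles used to check the fast implementations.

These deliberately work on dense signed adjacency arrays with an explicit
O(N^2) double loop over node pairs, inspecting matrix entries directly --
a separate code path from the edge-set based counting in the package.
"""


import numpy as np


def brute_force_multilink_counts(sig_dense, grn_dense, s_index, allowed_pairs=None):
    """Count (S, R) multilinks by scanning every node pair of dense matrices.

    ``sig_dense`` and ``grn_dense`` are signed arrays (+1 both ways for an
    undirected edge, +1/-1 for a directed one).  Collapse rules: a directed
    signaling edge counts once, with R read relative to its direction; an
    undirected signaling edge overlapping any regulatory edge counts once
    under (S, +1) and once under (S, -1); an undirected signaling edge with
    no regulatory overlap counts once under (S, 0).
    """
    a = np.asarray(sig_dense)
    b = np.asarray(grn_dense)
    n = a.shape[0]
    counts = {(s_index, r): 0 for r in (-1, 0, 1)}
    for i in range(n):
        for j in range(i + 1, n):
            if allowed_pairs is not None and (i, j) not in allowed_pairs:
                continue
            a1, a2 = a[i, j], a[j, i]
            b1, b2 = b[i, j], b[j, i]
            if a1 == 0 and a2 == 0:
                continue
            if a1 == 1 and a2 == 1:  # undirected signaling edge
                if b1 == 1 or b2 == 1:
                    counts[(s_index, 1)] += 1
                    counts[(s_index, -1)] += 1
                else:
                    counts[(s_index, 0)] += 1
                continue
            # directed signaling edge: orient so it runs u -> v
            if a1 == 1:
                bf, bb = b1, b2
            else:
                bf, bb = b2, b1
            if bf == 1:
                counts[(s_index, 1)] += 1
            if bb == 1:
                counts[(s_index, -1)] += 1
            if bf != 1 and bb != 1:
                counts[(s_index, 0)] += 1
    return counts


def brute_force_zero_counts(kegg_dense, grn_dense, allowed_pairs=None):
    """(0, 1) and (0, 0) counts by scanning every node pair."""
    a = np.asarray(kegg_dense)
    b = np.asarray(grn_dense)
    n = a.shape[0]
    zero_one = 0
    zero_zero_pairs = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            if allowed_pairs is not None and (i, j) not in allowed_pairs:
                continue
            n_pairs += 1
            sig = a[i, j] != 0 or a[j, i] != 0
            grn = b[i, j] != 0 or b[j, i] != 0
            if grn and not sig:
                zero_one += 1
            if not grn and not sig:
                zero_zero_pairs += 1
    return {(0, 1): zero_one, (0, 0): 2 * zero_zero_pairs}


def brute_force_simple_paths(graph_edges, source, target, k):
    """All simple paths by exhaustive DFS, sorted by (length, path), top k."""
    adjacency = {}
    for u, v in graph_edges:
        adjacency.setdefault(u, set()).add(v)
    paths = []

    def walk(node, seen, path):
        if node == target:
            paths.append(list(path))
            return
        for nxt in sorted(adjacency.get(node, ())):
            if nxt not in seen:
                seen.add(nxt)
                path.append(nxt)
                walk(nxt, seen, path)
                path.pop()
                seen.remove(nxt)

    walk(source, {source}, [source])
    paths.sort(key=lambda p: (len(p), p))
    return paths[:k]


def mann_whitney_auroc(ranking, labels):
    """AUROC as the normalized count of concordant positive-negative pairs.

    ``ranking`` lists items best-first; ties in rank are not supported (every
    item has a distinct rank).
    """
    pos = [i for i, item in enumerate(ranking) if labels[item] == 1]
    neg = [i for i, item in enumerate(ranking) if labels[item] == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    concordant = sum(1 for p in pos for q in neg if p < q)
    return concordant / (len(pos) * len(neg))


def two_sided_hypergeom_p(overlap, size_a, size_b, universe):
    """Two-tailed Fisher p by enumerating the hypergeometric pmf.

    Sums the probabilities of all overlap values whose pmf does not exceed
    the observed one (scipy's two-sided convention).
    """
    from math import comb

    def pmf(x):
        if x > min(size_a, size_b) or x < max(0, size_a + size_b - universe):
            return 0.0
        return (
            comb(size_a, x)
            * comb(universe - size_a, size_b - x)
            / comb(universe, size_b)
        )

    p_obs = pmf(overlap)
    total = 0.0
    for x in range(0, min(size_a, size_b) + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
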