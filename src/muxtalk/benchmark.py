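"""Baseline crosstalk methods and ROC/PR evaluation of ranked pathway pairs.

Four comparison methods are provided: node overlap and edge overlap (Fisher
exact tests with Benjamini-Hochberg correction), direct edges between
exclusive pathway node sets scored against the degree-preserving null
ensemble, and a receptor-to-TF K-shortest-paths statistic (chi) computed with
Yen's algorithm.  The chi closed form is a plug-in: the default statistic is
the number of connecting paths, which is a documented stand-in, not the
published chi formula from the shortest-path crosstalk literature.

Evaluation supports two modes.  Deterministic: ROC/PR over detected labeled
pairs only.  Stochastic: all labeled pairs enter; undetected pairs receive
random distinct ranks strictly below the last detected rank, re-shuffled
``n_shuffles`` times, and the AUCs are reported as mean and standard
deviation over shuffles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .crosstalk import _keggppi_digraph, exclusive_nodes
from .multilinks import multilink_stats
from .netbuild import KEGGPPI_LABEL, MultilayerNetwork

__all__ = [
    "BenchmarkLabels",
    "RankedEvaluation",
    "node_overlap_rank",
    "edge_overlap_rank",
    "direct_edge_rank",
    "yen_k_shortest",
    "path_count_statistic",
    "chi_rank",
    "evaluate",
    "precision_at_rank",
]


@dataclass
class BenchmarkLabels:
    """Ordered pathway-pair truth labels (1 = crosstalk, 0 = no crosstalk)."""

    labels: dict = field(default_factory=dict)
    universe: list = field(default_factory=list)

    def __post_init__(self):
        extra = set(self.labels) - set(self.universe)
        if extra:
            raise ValueError(f"labels outside the pair universe: {sorted(extra)[:3]}")

    @property
    def positives(self) -> set:
        return {p for p, v in self.labels.items() if v == 1}

    @property
    def negatives(self) -> set:
        return {p for p, v in self.labels.items() if v == 0}


@dataclass
class RankedEvaluation:
    """ROC/PR areas of one ranked list against benchmark labels."""

    auroc: float
    auprc: float
    mode: str
    n_detected: int
    n_shuffles: int = 0
    auroc_sd: float = 0.0
    auprc_sd: float = 0.0


def _overlap_rank(
    item_sets: Mapping[str, set], universe_size: int
) -> pd.DataFrame:
    """Fisher-exact overlap significance for every unordered pathway pair.

    The two-tailed test on the 2x2 table (shared, only-A, only-B, neither)
    over a universe of ``universe_size`` items; BH step-up FDR across all
    pairs; the same value is assigned to both orderings of a pair so every
    method ranks the same ordered-pair universe.
    """
    if universe_size <= 0:
        raise ValueError("empty universe")
    pathways = sorted(item_sets)
    rows = []
    for a, b in combinations(pathways, 2):
        sa, sb = item_sets[a], item_sets[b]
        ov = len(sa & sb)
        only_a = len(sa) - ov
        only_b = len(sb) - ov
        neither = universe_size - ov - only_a - only_b
        if neither < 0:
            raise ValueError("universe smaller than the union of item sets")
        _, p = fisher_exact([[ov, only_a], [only_b, neither]], alternative="two-sided")
        rows.append({"a": a, "b": b, "overlap": ov, "p": p})
    frame = pd.DataFrame(rows)
    frame["fdr"] = multipletests(frame["p"], method="fdr_bh")[1]
    frame["detected"] = frame["overlap"] > 0
    ordered = []
    for row in frame.itertuples(index=False):
        for pa, pb in ((row.a, row.b), (row.b, row.a)):
            ordered.append(
                {
                    "pathway_a": pa,
                    "pathway_b": pb,
                    "overlap": row.overlap,
                    "p": row.p,
                    "fdr": row.fdr,
                    "detected": row.detected,
                }
            )
    out = pd.DataFrame(ordered)
    det = out[out["detected"]].sort_values(
        ["fdr", "p", "pathway_a", "pathway_b"], kind="mergesort"
    )
    ranks = {
        (r.pathway_a, r.pathway_b): i + 1 for i, r in enumerate(det.itertuples(index=False))
    }
    out["rank"] = [
        ranks.get((r.pathway_a, r.pathway_b)) for r in out.itertuples(index=False)
    ]
    return out.sort_values(
        ["detected", "rank"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def node_overlap_rank(
    membership: Mapping[str, set], universe_genes: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Rank pathway pairs by the significance of their gene-set overlap."""
    sets = {p: set(m) for p, m in membership.items()}
    universe = (
        set().union(*sets.values()) if universe_genes is None else set(universe_genes)
    )
    return _overlap_rank(sets, len(universe))


def edge_overlap_rank(
    edge_sets: Mapping[str, set],
    universe_genes: Iterable[str],
    ordered: bool = True,
) -> pd.DataFrame:
    """Rank pathway pairs by the significance of their shared-edge overlap.

    The total number of possible edges is N*(N-1) ordered positions over the
    union gene set (the signaling multigraph is directed); set
    ``ordered=False`` for the unordered N*(N-1)/2 convention.
    """
    n = len(set(universe_genes))
    total = n * (n - 1) if ordered else n * (n - 1) // 2
    return _overlap_rank({p: set(e) for p, e in edge_sets.items()}, total)


def direct_edge_rank(
    multilayer: MultilayerNetwork,
    ensemble,
    membership: Mapping[str, set],
    n_rand: int = 100,
) -> pd.DataFrame:
    """Rank pairs by direct edges between exclusive node sets vs the null.

    The count of collapsed-signaling-layer edges with one endpoint in each
    exclusive set is compared against the same count on randomized KEGGPPI
    instances; pairs are ranked by empirical p ascending, then z descending.
    """
    idx = multilayer.gene_index
    pathways = sorted(membership)
    rows = []
    for a in pathways:
        for b in pathways:
            if a == b:
                continue
            ex_a, ex_b, _ = exclusive_nodes(a, b, membership)
            ia = {idx[g] for g in ex_a if g in idx}
            ib = {idx[g] for g in ex_b if g in idx}
            if not ia or not ib:
                rows.append(
                    {"pathway_a": a, "pathway_b": b, "count": 0, "z": math.nan,
                     "p": math.nan, "detected": False}
                )
                continue
            count = _edges_between(multilayer.keggppi, ia, ib)
            alloc = ensemble.allocate(
                (KEGGPPI_LABEL, KEGGPPI_LABEL), n_rand, f"direct:{a}->{b}"
            )
            nulls = [
                _edges_between(ensemble.instances[KEGGPPI_LABEL][i], ia, ib)
                for i, _ in alloc
            ]
            st = multilink_stats(count, nulls, n_rand)
            rows.append(
                {"pathway_a": a, "pathway_b": b, "count": count, "z": st.z,
                 "p": st.p_emp, "detected": True}
            )
    out = pd.DataFrame(rows)
    return _rank_by_significance(out)


def _rank_by_significance(out: pd.DataFrame) -> pd.DataFrame:
    """Rank detected pairs: over-represented (z > 0) first by p ascending
    then z descending, under- or un-represented pairs after."""
    out = out.copy()
    out["_under"] = ~(out["z"] > 0)
    det = out[out["detected"]].sort_values(
        ["_under", "p", "z", "pathway_a", "pathway_b"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    ranks = {
        (r.pathway_a, r.pathway_b): i + 1 for i, r in enumerate(det.itertuples(index=False))
    }
    out["rank"] = [
        ranks.get((r.pathway_a, r.pathway_b)) for r in out.itertuples(index=False)
    ]
    out = out.drop(columns=["_under"])
    return out.sort_values(
        ["detected", "rank"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _edges_between(layer, ia: set, ib: set) -> int:
    count = 0
    for i, j in layer.directed:
        if (i in ia and j in ib) or (i in ib and j in ia):
            count += 1
    for i, j in layer.undirected:
        if (i in ia and j in ib) or (i in ib and j in ia):
            count += 1
    return count


def yen_k_shortest(graph: nx.DiGraph, source, target, k: int) -> list:
    """Up to K loopless shortest paths, by length then lexicographically.

    Unit edge weights; fewer than K paths are returned when fewer exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for node in (source, target):
        if node not in graph:
            raise KeyError(f"node absent from graph: {node!r}")
    paths: list = []
    try:
        gen = nx.shortest_simple_paths(graph, source, target)
        for path in gen:
            if len(paths) >= k and len(path) > len(paths[k - 1]):
                break
            paths.append(path)
    except nx.NetworkXNoPath:
        return []
    paths.sort(key=lambda p: (len(p), p))
    return paths[:k]


def path_count_statistic(paths: Sequence[Sequence]) -> float:
    """Default plug-in crosstalk statistic: the number of connecting paths."""
    return float(len(paths))


def chi_rank(
    multilayer: MultilayerNetwork,
    receptors: Iterable[str],
    tfs: Iterable[str],
    membership: Mapping[str, set],
    k: int = 10,
    chi_fn: Optional[Callable[[Sequence[Sequence]], float]] = None,
    ensemble=None,
    n_rand: int = 100,
) -> pd.DataFrame:
    """Rank pairs by a statistic over receptor(A) -> TF(B) K-shortest paths.

    ``chi_fn`` maps the list of connecting paths to a scalar; it must be
    supplied or left as the default path-count statistic.  Pairs lacking
    receptors, TFs, or connecting paths are undetected.  z and empirical p
    come from repeating the computation on randomized KEGGPPI instances.
    """
    if chi_fn is None:
        raise ValueError(
            "no crosstalk statistic supplied: pass chi_fn (e.g. "
            "muxtalk.benchmark.path_count_statistic)"
        )
    idx = multilayer.gene_index
    receptors = set(receptors)
    tfs = set(tfs)
    pathways = sorted(membership)
    graph = _keggppi_digraph(multilayer.keggppi)
    null_graphs = None

    def pair_chi(g, rec_idx, tf_idx):
        paths = []
        for r in sorted(rec_idx):
            for t in sorted(tf_idx):
                if r == t or r not in g or t not in g:
                    continue
                paths.extend(yen_k_shortest(g, r, t, k))
        return paths

    rows = []
    for a in pathways:
        rec_a = {idx[g] for g in (receptors & set(membership[a])) if g in idx}
        for b in pathways:
            if a == b:
                continue
            tf_b = {idx[g] for g in (tfs & set(membership[b])) if g in idx}
            if not rec_a or not tf_b:
                rows.append({"pathway_a": a, "pathway_b": b, "chi": math.nan,
                             "z": math.nan, "p": math.nan, "detected": False})
                continue
            paths = pair_chi(graph, rec_a, tf_b)
            if not paths:
                rows.append({"pathway_a": a, "pathway_b": b, "chi": math.nan,
                             "z": math.nan, "p": math.nan, "detected": False})
                continue
            chi = chi_fn(paths)
            if ensemble is not None:
                if null_graphs is None:
                    null_graphs = {}
                alloc = ensemble.allocate(
                    (KEGGPPI_LABEL, KEGGPPI_LABEL), n_rand, f"chi:{a}->{b}"
                )
                nulls = []
                for i, _ in alloc:
                    if i not in null_graphs:
                        null_graphs[i] = _keggppi_digraph(
                            ensemble.instances[KEGGPPI_LABEL][i]
                        )
                    nulls.append(chi_fn(pair_chi(null_graphs[i], rec_a, tf_b)))
                st = multilink_stats(chi, nulls, n_rand)
                rows.append({"pathway_a": a, "pathway_b": b, "chi": chi,
                             "z": st.z, "p": st.p_emp, "detected": True})
            else:
                rows.append({"pathway_a": a, "pathway_b": b, "chi": chi,
                             "z": math.nan, "p": math.nan, "detected": True})
    out = pd.DataFrame(rows)
    if ensemble is not None:
        return _rank_by_significance(out)
    det = out[out["detected"]].sort_values(
        ["chi", "pathway_a", "pathway_b"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    ranks = {
        (r.pathway_a, r.pathway_b): i + 1 for i, r in enumerate(det.itertuples(index=False))
    }
    out["rank"] = [
        ranks.get((r.pathway_a, r.pathway_b)) for r in out.itertuples(index=False)
    ]
    return out.sort_values(
        ["detected", "rank"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _auc_from_ranks(rank_of: Mapping, labels: BenchmarkLabels, pairs) -> tuple[float, float]:
    y = np.array([labels.labels[p] for p in pairs])
    # lower rank = stronger crosstalk call = higher score
    scores = np.array([-rank_of[p] for p in pairs], dtype=float)
    return float(roc_auc_score(y, scores)), float(average_precision_score(y, scores))


def evaluate(
    ranked: pd.DataFrame,
    labels: BenchmarkLabels,
    mode: str = "deterministic",
    n_shuffles: int = 1000,
    seed: int = 0,
) -> RankedEvaluation:
    """ROC/PR areas of a ranked pathway-pair table against truth labels.

    ``ranked`` needs columns pathway_a, pathway_b, rank, detected.
    Deterministic mode scores the detected labeled pairs only.  Stochastic
    mode scores every labeled pair, assigning the undetected ones random
    distinct ranks strictly below the last detected rank in each of
    ``n_shuffles`` shuffles; with zero undetected pairs it reduces exactly to
    the deterministic result with sd = 0.
    """
    rank_of = {}
    detected_pairs = []
    for row in ranked.itertuples(index=False):
        pair = (row.pathway_a, row.pathway_b)
        if bool(row.detected) and pair in labels.labels:
            rank_of[pair] = int(row.rank)
            detected_pairs.append(pair)
    if mode == "deterministic":
        pairs = detected_pairs
        y = [labels.labels[p] for p in pairs]
        if len(set(y)) < 2:
            raise ValueError("need both positive and negative labeled pairs")
        auroc, auprc = _auc_from_ranks(rank_of, labels, pairs)
        return RankedEvaluation(auroc, auprc, "deterministic", len(detected_pairs))
    if mode != "stochastic":
        raise ValueError(f"unknown mode: {mode!r}")
    all_pairs = [p for p in labels.universe if p in labels.labels]
    undetected = [p for p in all_pairs if p not in rank_of]
    y = [labels.labels[p] for p in all_pairs]
    if len(set(y)) < 2:
        raise ValueError("need both positive and negative labeled pairs")
    if not undetected:
        # the modes coincide exactly: every labeled pair has a fixed rank
        auroc, auprc = _auc_from_ranks(rank_of, labels, all_pairs)
        return RankedEvaluation(
            auroc, auprc, "stochastic", len(detected_pairs), n_shuffles, 0.0, 0.0
        )
    floor = max(rank_of.values(), default=0)
    rng = np.random.default_rng(seed)
    aurocs, auprcs = [], []
    for _ in range(n_shuffles):
        shuffled = dict(rank_of)
        perm = rng.permutation(len(undetected))
        for pos, p in zip(perm, undetected):
            shuffled[p] = floor + 1 + int(pos)
        roc, pr = _auc_from_ranks(shuffled, labels, all_pairs)
        aurocs.append(roc)
        auprcs.append(pr)
    return RankedEvaluation(
        float(np.mean(aurocs)),
        float(np.mean(auprcs)),
        "stochastic",
        len(detected_pairs),
        n_shuffles,
        float(np.std(aurocs)),
        float(np.std(auprcs)),
    )


def precision_at_rank(
    ranked_pairs: Sequence, positives: Iterable, top_k: int
) -> list[float]:
    """Precision among the top-k ranked pairs, for k = 1..top_k."""
    if top_k > len(ranked_pairs):
        raise ValueError("top_k exceeds the number of ranked pairs")
    pos = set(positives)
    hits = 0
    out = []
    for k, pair in enumerate(ranked_pairs[:top_k], start=1):
        if pair in pos:
            hits += 1
        out.append(hits / k)
    return out
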