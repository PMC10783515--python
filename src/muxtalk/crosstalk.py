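"""Crosstalk inference from multilink over-representation between pathways.

For an ordered pathway pair (A, B) the candidate edge positions are either
the direct edges between the mutually exclusive node sets of A and B
(``between``) or the edges on intermediary shortest paths connecting them on
the collapsed signaling layer (``shortest``).  Multilinks of type (S, +1) and
(S, -1) -- a signaling edge coinciding with a regulatory edge in either
relative direction -- act as proxies of crosstalk: a pair is deemed
crosstalking when at least one such type is significantly over-represented
(p_emp <= alpha, z > 0) against the degree-preserving null ensemble.

Detected pairs are ranked by the composite score

    score = 1000 * n_sig - log10(p_best + 0.001) * z_best      (sd != 0)
    score = 1000 * n_sig - log10(p_best + 0.001)               (sd  = 0)

which encodes the three-key order (most significant types, lowest p, highest
z); the sd = 0 branch applies when the best type's null distribution is
degenerate and its z-score therefore undefined or infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .multilinks import (
    count_multilinks,
    count_zero_signaling,
    multilink_positions,
    multilink_stats,
    normalize_pairs,
    zero_signaling_positions,
)
from .netbuild import (
    GRN_LABEL,
    KEGGPPI_LABEL,
    LAYER_LABELS,
    PPI,
    LayerMatrix,
    MultilayerNetwork,
)

__all__ = [
    "muxtalk_score",
    "PairSubset",
    "CrosstalkResult",
    "exclusive_nodes",
    "between_positions",
    "shortest_positions",
    "assess_pair",
    "rank_pairs",
    "leave_one_layer_out",
]

ALPHA_DEFAULT = 0.05


def muxtalk_score(n_sig: int, p_best: float, z_best: float = math.nan,
                  sigma_zero: bool = False) -> float:
    """Composite ranking score for a detected pathway pair.

    1000 * n_sig - log10(p_best + 0.001) * z_best, with the z factor omitted
    when the best type's null standard deviation is zero (z undefined or
    infinite).  The 0.001 offset keeps the logarithm finite at p = 0.
    """
    if sigma_zero:
        return 1000.0 * n_sig - math.log10(p_best + 0.001)
    return 1000.0 * n_sig - math.log10(p_best + 0.001) * z_best


@dataclass
class PairSubset:
    """Candidate edge positions for one ordered pathway pair.

    Positions are ordered index pairs including both orientations of each
    candidate edge so the signed counting sees directed edges either way; no
    position touches a gene common to both pathways.
    """

    pair: tuple[str, str]
    method: str  # "between" | "shortest"
    sp_threshold: Optional[int] = None
    positions: set = field(default_factory=set)
    intermediary_nodes: set = field(default_factory=set)
    ex_a: set = field(default_factory=set)
    ex_b: set = field(default_factory=set)
    nodes_a: set = field(default_factory=set)
    nodes_b: set = field(default_factory=set)


@dataclass
class CrosstalkResult:
    """Per ordered pathway pair: significance summary, score and mediators."""

    pair: tuple[str, str]
    method: str
    sp_threshold: Optional[int] = None
    detected: bool = False
    n_sig: int = 0
    p_best: float = math.nan
    z_best: float = math.nan
    sigma_zero_flag: bool = False
    score: float = math.nan
    significant_types: list = field(default_factory=list)
    mediators: list = field(default_factory=list)
    type_stats: dict = field(default_factory=dict)


def exclusive_nodes(
    pathway_a: str, pathway_b: str, membership: Mapping[str, set]
) -> tuple[set, set, set]:
    """Mutually exclusive and common gene sets of two pathways."""
    for p in (pathway_a, pathway_b):
        if p not in membership:
            raise KeyError(f"unknown pathway id: {p!r}")
    a = set(membership[pathway_a])
    b = set(membership[pathway_b])
    return a - b, b - a, a & b


def between_positions(
    multilayer: MultilayerNetwork, ex_a: Iterable[str], ex_b: Iterable[str]
) -> PairSubset:
    """Direct-edge candidate positions between exclusive node sets."""
    idx = multilayer.gene_index
    ia = {idx[g] for g in ex_a if g in idx}
    ib = {idx[g] for g in ex_b if g in idx}
    positions = set()
    for a in ia:
        for b in ib:
            positions.add((a, b))
            positions.add((b, a))
    return PairSubset(
        pair=("", ""), method="between", positions=positions, ex_a=ia, ex_b=ib
    )


def _keggppi_digraph(layer: LayerMatrix) -> nx.DiGraph:
    g = nx.DiGraph()
    for i, j in sorted(layer.directed):
        g.add_edge(i, j)
    for i, j in sorted(layer.undirected):
        g.add_edge(i, j)
        g.add_edge(j, i)
    return g


def shortest_positions(
    multilayer: MultilayerNetwork,
    ex_a: Iterable[str],
    ex_b: Iterable[str],
    pathway_a_nodes: Iterable[str],
    pathway_b_nodes: Iterable[str],
    sp_threshold: Optional[int] = None,
    keggppi: Optional[LayerMatrix] = None,
) -> PairSubset:
    """Shortest-path candidate positions between exclusive node sets.

    For each (a in exclusive(A), b in exclusive(B)) one shortest directed
    path is computed on the collapsed signaling layer (undirected edges are
    traversable both ways).  A path is retained only when every internal node
    lies outside A union B (these are the intermediary nodes) and, if
    ``sp_threshold`` is given, when it has at most that many intermediaries.
    Positions are the union of edges over all retained paths, plus
    transposes.  ``keggppi`` overrides the layer used for path search (the
    null computation passes a randomized instance here).
    """
    idx = multilayer.gene_index
    ia = sorted(idx[g] for g in ex_a if g in idx)
    ib = sorted(idx[g] for g in ex_b if g in idx)
    forbidden = {idx[g] for g in set(pathway_a_nodes) | set(pathway_b_nodes) if g in idx}
    layer = multilayer.keggppi if keggppi is None else keggppi
    graph = _keggppi_digraph(layer)
    positions: set = set()
    intermediaries: set = set()
    for a in ia:
        if a not in graph:
            continue
        # single-source BFS gives the shortest path to every reachable target
        preds = nx.predecessor(graph, a)
        for b in ib:
            if b == a or b not in preds:
                continue
            # reconstruct one deterministic shortest path a -> b
            path = [b]
            while path[-1] != a:
                path.append(min(preds[path[-1]]))
            path.reverse()
            internal = path[1:-1]
            if any(node in forbidden for node in internal):
                continue
            if sp_threshold is not None and len(internal) > sp_threshold:
                continue
            intermediaries.update(internal)
            for u, v in zip(path[:-1], path[1:]):
                positions.add((u, v))
                positions.add((v, u))
    return PairSubset(
        pair=("", ""),
        method="shortest",
        sp_threshold=sp_threshold,
        positions=positions,
        intermediary_nodes=intermediaries,
        ex_a=set(ia),
        ex_b=set(ib),
    )


def _proxy_types(type_stats: Mapping, include_zero: bool) -> list:
    out = []
    for (s, r) in type_stats:
        if r == 0:
            continue
        if s == 0 and not include_zero:
            continue
        out.append((s, r))
    return out


def _score_from_stats(
    type_stats: Mapping,
    alpha: float,
    include_zero: bool,
    exclude_types: Optional[set] = None,
) -> tuple[bool, int, float, float, bool, float, list]:
    """(detected, n_sig, p_best, z_best, sigma_zero, score, significant_types)."""
    candidates = [
        t
        for t in _proxy_types(type_stats, include_zero)
        if (exclude_types is None or t not in exclude_types) and type_stats[t].c_a > 0
    ]
    if not candidates:
        return False, 0, math.nan, math.nan, False, math.nan, []
    sig = [
        t
        for t in candidates
        if type_stats[t].p_emp <= alpha
        and (type_stats[t].z > 0 if not math.isnan(type_stats[t].z) else False)
    ]
    n_sig = len(sig)
    # best type: lowest p; ties broken by highest *finite* z -- a degenerate
    # null (sd = 0) leaves z undefined or infinite, which cannot serve the
    # highest-z ranking key, so such types yield only when nothing else ties
    best = min(candidates, key=lambda t: (type_stats[t].p_emp, _neg_z(type_stats[t].z)))
    p_best = type_stats[best].p_emp
    sigma_zero = type_stats[best].sigma_zero
    finite_z = [type_stats[t].z for t in candidates if math.isfinite(type_stats[t].z)]
    z_best = max(finite_z) if finite_z else math.nan
    sigma_zero = sigma_zero or not finite_z
    score = muxtalk_score(n_sig, p_best, z_best, sigma_zero)
    return True, n_sig, p_best, z_best, sigma_zero, score, sorted(sig)


def _neg_z(z: float) -> tuple[int, float]:
    """Sort key placing finite z (descending) before +inf, NaN, -inf."""
    if math.isnan(z):
        return (2, 0.0)
    if math.isinf(z):
        return (1, 0.0) if z > 0 else (3, 0.0)
    return (0, -z)


def assess_pair(
    multilayer: MultilayerNetwork,
    ensemble,
    subset: PairSubset,
    n_rand: int = 100,
    alpha: float = ALPHA_DEFAULT,
    include_zero: bool = True,
) -> CrosstalkResult:
    """Multilink statistics and MuXTalk score for one ordered pathway pair.

    For ``between`` subsets the candidate positions are fixed and the null
    counts use randomized signaling/GRN instance pairs.  For ``shortest``
    subsets the candidate positions are re-derived on the randomized KEGGPPI
    instance allocated to the same null index as the signaling-layer
    instance, so each draw sees one coherent randomized multilayer.
    ``include_zero`` adds (0, 1) -- a pure regulatory edge between the
    pathways with no signaling edge -- to the crosstalk proxy types.
    """
    result = CrosstalkResult(
        pair=subset.pair, method=subset.method, sp_threshold=subset.sp_threshold
    )
    if not subset.positions:
        return result
    positions = subset.positions
    allowed = normalize_pairs(positions)
    context = f"{subset.pair[0]}->{subset.pair[1]}:{subset.method}:{subset.sp_threshold}"
    grn = multilayer.grn
    shortest = subset.method == "shortest"

    null_positions_cache: dict[int, tuple] = {}

    def positions_for_null(i: int):
        """(ordered positions, unordered view) of the k-th null's subset."""
        if not shortest:
            return positions, allowed
        if i not in null_positions_cache:
            rnd_kegg = ensemble.instances[KEGGPPI_LABEL][i]
            sub = shortest_positions(
                multilayer,
                [multilayer.genes[k] for k in subset.ex_a],
                [multilayer.genes[k] for k in subset.ex_b],
                [multilayer.genes[k] for k in subset.nodes_a] if subset.nodes_a else [],
                [multilayer.genes[k] for k in subset.nodes_b] if subset.nodes_b else [],
                subset.sp_threshold,
                keggppi=rnd_kegg,
            )
            null_positions_cache[i] = (sub.positions, normalize_pairs(sub.positions))
        return null_positions_cache[i]

    type_stats: dict = {}
    for s in sorted(LAYER_LABELS):
        label = LAYER_LABELS[s]
        layer = multilayer.layers[label]
        actual = count_multilinks(layer, grn, s, positions, allowed=allowed)
        alloc = ensemble.allocate((label, GRN_LABEL), n_rand, context)
        nulls = {key: [] for key in actual}
        for i, j in alloc:
            null_pos, null_allowed = positions_for_null(i)
            rnd = count_multilinks(
                ensemble.instances[label][i],
                ensemble.instances[GRN_LABEL][j],
                s,
                null_pos,
                allowed=null_allowed,
            )
            for key in nulls:
                nulls[key].append(rnd[key])
        for key, c in actual.items():
            type_stats[key] = multilink_stats(c, nulls[key], n_rand)

    actual0 = count_zero_signaling(multilayer.keggppi, grn, positions, allowed=allowed)
    alloc = ensemble.allocate((KEGGPPI_LABEL, GRN_LABEL), n_rand, context)
    nulls0 = {key: [] for key in actual0}
    for i, j in alloc:
        null_pos, null_allowed = positions_for_null(i)
        rnd = count_zero_signaling(
            ensemble.instances[KEGGPPI_LABEL][i],
            ensemble.instances[GRN_LABEL][j],
            null_pos,
            allowed=null_allowed,
        )
        for key in nulls0:
            nulls0[key].append(rnd[key])
    for key, c in actual0.items():
        type_stats[key] = multilink_stats(c, nulls0[key], n_rand)

    result.type_stats = type_stats
    detected, n_sig, p_best, z_best, sigma_zero, score, sig = _score_from_stats(
        type_stats, alpha, include_zero
    )
    result.detected = detected
    if not detected:
        return result
    result.n_sig = n_sig
    result.p_best = p_best
    result.z_best = z_best
    result.sigma_zero_flag = sigma_zero
    result.score = score
    result.significant_types = sig

    for s, r in sig:
        if s == 0:
            pos = zero_signaling_positions(multilayer.keggppi, grn, positions)
        else:
            layer = multilayer.layers[LAYER_LABELS[s]]
            pos = multilink_positions(layer, grn, s, positions)[(s, r)]
        for edge in pos:
            result.mediators.append((edge, (s, r)))
    return result


def rank_pairs(results: Sequence[CrosstalkResult]) -> pd.DataFrame:
    """Rank pathway pairs by MuXTalk score.

    Detected pairs are sorted by score descending with lexicographic
    (pathway_a, pathway_b) tie-break; undetected pairs follow, unranked.
    """
    if not results:
        raise ValueError("rank_pairs requires at least one result")
    detected = [r for r in results if r.detected]
    undetected = [r for r in results if not r.detected]
    detected.sort(key=lambda r: (-r.score, r.pair))
    undetected.sort(key=lambda r: r.pair)
    rows = []
    for rank, r in enumerate(detected, start=1):
        rows.append(_row(r, rank))
    for r in undetected:
        rows.append(_row(r, None))
    return pd.DataFrame(rows)


def _row(r: CrosstalkResult, rank) -> dict:
    return {
        "pathway_a": r.pair[0],
        "pathway_b": r.pair[1],
        "method": r.method,
        "sp": r.sp_threshold,
        "rank": rank,
        "n_sig": r.n_sig,
        "p_best": r.p_best,
        "z_best": r.z_best,
        "score": r.score,
        "detected": r.detected,
        "sig_types": ";".join(f"({s},{x})" for s, x in r.significant_types),
    }


def leave_one_layer_out(
    results: Sequence[CrosstalkResult],
    left_out_layer: str,
    alpha: float = ALPHA_DEFAULT,
    include_zero: bool = True,
) -> pd.DataFrame:
    """Re-rank pairs excluding significant multilink types on one layer.

    Only the *significant* multilinks associated with the left-out layer are
    dropped when recomputing n_sig, p_best, z_best and the score, so leaving
    out a layer that carries no significant multilink anywhere is an exact
    no-op.  A pair whose significance rested entirely on the left-out layer
    (n_sig drops to zero) becomes undetected for ranking purposes.

    The PPI layer cannot be left out: it is the connective tissue of the
    collapsed signaling layer and removing it would invalidate the
    shortest-path subsets themselves, not just the multilink types.
    """
    if left_out_layer == PPI:
        raise ValueError(
            "the PPI layer cannot be left out: it plays a crucial role in "
            "connecting the signaling pathways"
        )
    label_to_s = {v: k for k, v in LAYER_LABELS.items()}
    if left_out_layer not in label_to_s:
        raise ValueError(f"not an interaction-specific layer: {left_out_layer!r}")
    s_out = label_to_s[left_out_layer]
    adjusted = []
    for r in results:
        excluded = {t for t in r.significant_types if t[0] == s_out}
        if not r.detected or not excluded:
            adjusted.append(r)
            continue
        nr = CrosstalkResult(pair=r.pair, method=r.method, sp_threshold=r.sp_threshold)
        nr.type_stats = r.type_stats
        detected, n_sig, p_best, z_best, sigma_zero, score, sig = _score_from_stats(
            r.type_stats, alpha, include_zero, exclude_types=excluded
        )
        if detected and n_sig == 0 and r.n_sig > 0:
            detected = False
        nr.detected = detected
        if detected:
            nr.n_sig = n_sig
            nr.p_best = p_best
            nr.z_best = z_best
            nr.sigma_zero_flag = sigma_zero
            nr.score = score
            nr.significant_types = sig
        adjusted.append(nr)
    return rank_pairs(adjusted)
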