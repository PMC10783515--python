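"""Multilink enumeration, counting and ensemble statistics.

A multilink records, for one node pair, the joint edge state across the
signaling and regulatory layers as a pair of integers (S, R): S in [0, 11] is
the signaling component (0 = no signaling edge, 1-11 one of the typed
signaling layers) and R in {-1, 0, 1} is the regulatory component, whose sign
encodes the direction of the GRN edge *relative to* the signaling edge.  This
gives 12 x 3 = 36 multilink types.

Counting conventions (collapse rules)
-------------------------------------
The signed fill stores a directed edge i->j as +1/-1 at the two symmetric
positions, so the pattern (s, r) at (i, j) and (-s, -r) at (j, i) are
equivalent representations of one multilink and contribute a single count.
An undirected signaling edge overlapping a GRN edge has no intrinsic
reference direction, so it contributes one count to (S, +1) *and* one to
(S, -1), making those two tallies exactly equal for undirected-only layers.
Undirected signaling edges with no GRN overlap are corrected for double
counting and tallied once under (S, 0).  (0, R) multilinks (GRN edge with no
signaling edge) are counted on the collapsed KEGGPPI layer to avoid
multiple-counting across typed layers; the (0, 1)/(0, -1) pair is
indistinguishable and counted once under the canonical (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import math

import numpy as np
import pandas as pd

from .netbuild import LayerMatrix

__all__ = [
    "N_MULTILINK_TYPES",
    "all_multilink_types",
    "encode_multilink",
    "decode_multilink",
    "normalize_pairs",
    "count_multilinks",
    "multilink_positions",
    "count_zero_signaling",
    "zero_signaling_positions",
    "MultilinkStat",
    "multilink_stats",
    "MultilinkProfile",
    "profile_subset",
]

N_MULTILINK_TYPES = 36


def all_multilink_types() -> list[tuple[int, int]]:
    """The 36 canonical (S, R) multilink types."""
    return [(s, r) for s in range(12) for r in (-1, 0, 1)]


def encode_multilink(s: int, r: int) -> int:
    """Injective hash of a multilink type onto [0, 36)."""
    if not (0 <= s <= 11):
        raise ValueError(f"signaling component out of range: {s}")
    if r not in (-1, 0, 1):
        raise ValueError(f"regulatory component out of range: {r}")
    return 3 * s + (r + 1)


def decode_multilink(code: int) -> tuple[int, int]:
    """Exact inverse of :func:`encode_multilink`."""
    if not (0 <= code < N_MULTILINK_TYPES):
        raise ValueError(f"multilink hash out of range: {code}")
    return code // 3, code % 3 - 1


def normalize_pairs(restrict_pairs: Optional[Iterable[tuple[int, int]]]):
    """Unordered-pair view of an ordered position set (None passes through).

    Callers that count against many null instances should normalize once and
    pass the result via the ``allowed`` parameter of the counting functions.
    """
    if restrict_pairs is None:
        return None
    return frozenset((min(i, j), max(i, j)) for i, j in restrict_pairs)


def _grn_lookup(grn: LayerMatrix):
    arcs = grn.directed
    und = grn.undirected

    def has_arc(i: int, j: int) -> bool:
        return (i, j) in arcs or (min(i, j), max(i, j)) in und

    return has_arc


def count_multilinks(
    s_layer: LayerMatrix,
    r_layer: LayerMatrix,
    s_index: int,
    restrict_pairs: Optional[Iterable[tuple[int, int]]] = None,
    allowed=None,
) -> dict[tuple[int, int], int]:
    """Count (S, R) multilinks whose signaling component lies on ``s_layer``.

    ``restrict_pairs`` confines counting to the given matrix positions (an
    unordered pair is considered if either orientation is listed; both
    orientations of candidate edges are visible to the signed counting).
    ``allowed`` may carry the precomputed :func:`normalize_pairs` view.
    """
    if s_layer.n != r_layer.n:
        raise ValueError("layer shape mismatch")
    if allowed is None:
        allowed = normalize_pairs(restrict_pairs)
    has_arc = _grn_lookup(r_layer)
    s = int(s_index)
    counts = {(s, -1): 0, (s, 0): 0, (s, 1): 0}
    for i, j in s_layer.directed:
        if allowed is not None and (min(i, j), max(i, j)) not in allowed:
            continue
        fwd = has_arc(i, j)
        bwd = has_arc(j, i)
        if fwd:
            counts[(s, 1)] += 1
        if bwd:
            counts[(s, -1)] += 1
        if not fwd and not bwd:
            counts[(s, 0)] += 1
    for i, j in s_layer.undirected:
        if allowed is not None and (i, j) not in allowed:
            continue
        if has_arc(i, j) or has_arc(j, i):
            counts[(s, 1)] += 1
            counts[(s, -1)] += 1
        else:
            counts[(s, 0)] += 1
    return counts


def multilink_positions(
    s_layer: LayerMatrix,
    r_layer: LayerMatrix,
    s_index: int,
    restrict_pairs: Optional[Iterable[tuple[int, int]]] = None,
) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Concrete edge positions realizing each (S, R) multilink.

    Positions are oriented along the signaling edge for directed edges and as
    (min, max) for undirected ones.  Companion to :func:`count_multilinks`:
    ``len(positions[t])`` equals the count for every R != 0 type (undirected
    signaling edges appear under both (S, 1) and (S, -1)).
    """
    if s_layer.n != r_layer.n:
        raise ValueError("layer shape mismatch")
    allowed = normalize_pairs(restrict_pairs)
    has_arc = _grn_lookup(r_layer)
    s = int(s_index)
    out: dict[tuple[int, int], list[tuple[int, int]]] = {
        (s, -1): [],
        (s, 0): [],
        (s, 1): [],
    }
    for i, j in s_layer.directed:
        if allowed is not None and (min(i, j), max(i, j)) not in allowed:
            continue
        fwd = has_arc(i, j)
        bwd = has_arc(j, i)
        if fwd:
            out[(s, 1)].append((i, j))
        if bwd:
            out[(s, -1)].append((i, j))
        if not fwd and not bwd:
            out[(s, 0)].append((i, j))
    for i, j in s_layer.undirected:
        if allowed is not None and (i, j) not in allowed:
            continue
        if has_arc(i, j) or has_arc(j, i):
            out[(s, 1)].append((i, j))
            out[(s, -1)].append((i, j))
        else:
            out[(s, 0)].append((i, j))
    return out


def count_zero_signaling(
    keggppi: LayerMatrix,
    r_layer: LayerMatrix,
    restrict_pairs: Optional[Iterable[tuple[int, int]]] = None,
    allowed=None,
) -> dict[tuple[int, int], int]:
    """Count (0, R) multilinks: GRN edges on positions with no signaling edge.

    Each qualifying GRN edge position is counted once under the canonical
    (0, 1).  (0, 0) -- neither edge -- is computed arithmetically from the
    number of ordered positions and the occupied ones, never by enumerating
    the dense complement.
    """
    if keggppi.n != r_layer.n:
        raise ValueError("layer shape mismatch")
    if allowed is None:
        allowed = normalize_pairs(restrict_pairs)
    sig_pairs = keggppi.edge_pairs()
    grn_pairs = r_layer.edge_pairs()
    zero_one = 0
    for pair in grn_pairs:
        if allowed is not None and pair not in allowed:
            continue
        if pair not in sig_pairs:
            zero_one += 1
    occupied = sig_pairs | grn_pairs
    if allowed is None:
        total_ordered = keggppi.n * (keggppi.n - 1)
        occupied_ordered = 2 * len(occupied)
    elif restrict_pairs is not None:
        positions = {(i, j) for i, j in restrict_pairs if i != j}
        total_ordered = len(positions)
        occupied_ordered = sum(
            1 for i, j in positions if (min(i, j), max(i, j)) in occupied
        )
    else:
        # only the unordered view is available; both orientations count
        total_ordered = 2 * len(allowed)
        occupied_ordered = 2 * sum(1 for pair in allowed if pair in occupied)
    return {(0, 1): zero_one, (0, 0): total_ordered - occupied_ordered}


def zero_signaling_positions(
    keggppi: LayerMatrix,
    r_layer: LayerMatrix,
    restrict_pairs: Optional[Iterable[tuple[int, int]]] = None,
) -> list[tuple[int, int]]:
    """GRN edge positions carrying no signaling edge, oriented along the GRN arc."""
    allowed = normalize_pairs(restrict_pairs)
    sig_pairs = keggppi.edge_pairs()
    out = []
    for i, j in r_layer.directed:
        pair = (min(i, j), max(i, j))
        if allowed is not None and pair not in allowed:
            continue
        if pair not in sig_pairs:
            out.append((i, j))
    for i, j in r_layer.undirected:
        if allowed is not None and (i, j) not in allowed:
            continue
        if (i, j) not in sig_pairs:
            out.append((i, j))
    return out


@dataclass(frozen=True)
class MultilinkStat:
    """Ensemble statistics for one multilink type.

    ``z`` is +/-inf when the null is degenerate (sd = 0) but the actual count
    deviates from the null mean, and NaN when the actual count equals every
    null count; ``sigma_zero`` flags both degenerate cases for the score
    formula downstream.
    """

    c_a: float
    null_mean: float
    null_sd: float
    z: float
    p_emp: float
    sigma_zero: bool


def multilink_stats(c_a: float, c_r: Iterable[float], n_rand: Optional[int] = None) -> MultilinkStat:
    """z-score and empirical p-value of an actual count against null counts.

    z = (c_a - <c_r>) / sigma(c_r).  The empirical p is the fraction of null
    instances at least as extreme as c_a, with the tail selected by the sign
    of z; z = 0 exactly yields p = 1 (no tail).  The raw fraction is reported
    without flooring, so p = 0 is possible when c_a exceeds every null count.
    """
    c_r = np.asarray(list(c_r), dtype=float)
    if n_rand is None:
        n_rand = len(c_r)
    if n_rand == 0 or len(c_r) == 0:
        raise ValueError("empirical statistics require at least one null instance")
    if len(c_r) != n_rand:
        raise ValueError(f"expected {n_rand} null counts, got {len(c_r)}")
    mean = float(c_r.mean())
    sd = float(c_r.std())  # population sd over the ensemble
    if sd == 0.0:
        if c_a == mean:
            return MultilinkStat(c_a, mean, sd, math.nan, 1.0, True)
        z = math.inf if c_a > mean else -math.inf
        if z > 0:
            p = float((c_r >= c_a).sum()) / n_rand
        else:
            p = float((c_r <= c_a).sum()) / n_rand
        return MultilinkStat(c_a, mean, sd, z, p, True)
    z = (c_a - mean) / sd
    if z > 0:
        p = float((c_r >= c_a).sum()) / n_rand
    elif z < 0:
        p = float((c_r <= c_a).sum()) / n_rand
    else:
        p = 1.0
    return MultilinkStat(c_a, mean, sd, z, p, False)


@dataclass
class MultilinkProfile:
    """Actual and null multilink counts, with z/p per type, for one edge subset."""

    subset_id: str
    counts: dict = field(default_factory=dict)
    null_counts: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    n_rand: int = 0

    def to_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for (s, r), c in sorted(self.counts.items()):
            st = self.stats.get((s, r))
            rows.append(
                {
                    "subset_id": self.subset_id,
                    "S": s,
                    "R": r,
                    "count": c,
                    "null_mean": st.null_mean if st else np.nan,
                    "null_sd": st.null_sd if st else np.nan,
                    "z": st.z if st else np.nan,
                    "p_emp": st.p_emp if st else np.nan,
                    "significant": bool(st and st.p_emp <= alpha and st.z > 0),
                }
            )
        return pd.DataFrame(rows)


def profile_subset(
    multilayer,
    ensemble,
    subset_id: str,
    restrict_pairs: Optional[Iterable[tuple[int, int]]] = None,
    n_rand: int = 100,
) -> MultilinkProfile:
    """Multilink profile of an edge subset against the null ensemble.

    For each typed signaling layer S the actual counts on the subset are
    compared with counts on deterministically allocated (signaling instance,
    GRN instance) pairs; (0, R) types are profiled on the KEGGPPI layer.
    Reproducible given the ensemble's master seed.
    """
    from .netbuild import GRN_LABEL, KEGGPPI_LABEL, LAYER_LABELS

    if restrict_pairs is not None:
        restrict_pairs = set(restrict_pairs)
    allowed = normalize_pairs(restrict_pairs)
    profile = MultilinkProfile(subset_id=subset_id, n_rand=n_rand)
    grn = multilayer.grn
    for s in sorted(LAYER_LABELS):
        label = LAYER_LABELS[s]
        layer = multilayer.layers[label]
        actual = count_multilinks(layer, grn, s, restrict_pairs, allowed=allowed)
        alloc = ensemble.allocate((label, GRN_LABEL), n_rand, subset_id)
        nulls = {key: [] for key in actual}
        for i, j in alloc:
            rnd = count_multilinks(
                ensemble.instances[label][i],
                ensemble.instances[GRN_LABEL][j],
                s,
                restrict_pairs,
                allowed=allowed,
            )
            for key in nulls:
                nulls[key].append(rnd[key])
        for key, c in actual.items():
            profile.counts[key] = c
            arr = np.asarray(nulls[key], dtype=float)
            profile.null_counts[key] = arr
            profile.stats[key] = multilink_stats(c, arr, n_rand)

    actual0 = count_zero_signaling(multilayer.keggppi, grn, restrict_pairs, allowed=allowed)
    alloc = ensemble.allocate((KEGGPPI_LABEL, GRN_LABEL), n_rand, subset_id)
    nulls0 = {key: [] for key in actual0}
    for i, j in alloc:
        rnd = count_zero_signaling(
            ensemble.instances[KEGGPPI_LABEL][i],
            ensemble.instances[GRN_LABEL][j],
            restrict_pairs,
            allowed=allowed,
        )
        for key in nulls0:
            nulls0[key].append(rnd[key])
    for key, c in actual0.items():
        profile.counts[key] = c
        arr = np.asarray(nulls0[key], dtype=float)
        profile.null_counts[key] = arr
        profile.stats[key] = multilink_stats(c, arr, n_rand)
    return profile
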