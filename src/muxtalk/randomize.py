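"""Degree-preserving layer randomization and null-ensemble management.

Null networks are produced by Maslov-Sneppen style pairwise edge rewiring:
two edges are picked at random and their endpoints exchanged, rejecting any
swap that would create a self-loop or a duplicate edge.  The swap budget
counts *attempts* (rejected attempts are not retried), which guarantees
termination on swap-poor graphs such as stars, where no legal swap exists and
the layer is returned unchanged.  Directed arcs are rewired with directed
swaps (preserving in- and out-degree sequences exactly); undirected edges are
rewired with double-edge swaps (preserving the undirected degree sequence).
Each layer of the multiplex is randomized independently, which breaks any
degree correlation between layers, and the signed-fill convention is
re-applied to the rewired edge sets.

Instances for null computations are drawn from the precomputed ensemble by a
deterministic hash-offset allocation rule, so every null statistic is exactly
reproducible from the master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .netbuild import LayerMatrix, MultilayerNetwork

__all__ = ["rewire_layer", "build_ensemble", "RandomEnsemble"]


def _rewire_directed(arcs: list, occupied: set, attempts: int, rng) -> None:
    """In-place directed swaps (a->b, c->d) -> (a->d, c->b)."""
    arcset = set(arcs)
    m = len(arcs)
    if m < 2:
        return
    choices = rng.integers(0, m, size=(attempts, 2))
    for k in range(attempts):
        i1, i2 = choices[k]
        if i1 == i2:
            continue
        a, b = arcs[i1]
        c, d = arcs[i2]
        if a == d or c == b:
            continue
        new1, new2 = (a, d), (c, b)
        if new1 == new2 or new1 in arcset or new2 in arcset:
            continue
        p1 = (min(a, d), max(a, d))
        p2 = (min(c, b), max(c, b))
        old1 = (min(a, b), max(a, b))
        old2 = (min(c, d), max(c, d))
        # Keep each unordered pair singly occupied so the signed fill stays
        # well defined ({-1, 0, +1} entries); the two old pairs vacate.
        if p1 == p2:
            continue
        if p1 in occupied and p1 != old1 and p1 != old2:
            continue
        if p2 in occupied and p2 != old1 and p2 != old2:
            continue
        arcs[i1] = new1
        arcs[i2] = new2
        arcset.discard((a, b))
        arcset.discard((c, d))
        arcset.add(new1)
        arcset.add(new2)
        occupied.discard(old1)
        occupied.discard(old2)
        occupied.add(p1)
        occupied.add(p2)


def _rewire_undirected(pairs: list, occupied: set, attempts: int, rng) -> None:
    """In-place double-edge swaps {a,b}, {c,d} -> {a,d}, {c,b}."""
    m = len(pairs)
    if m < 2:
        return
    choices = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=(attempts, 2))
    for k in range(attempts):
        i1, i2 = choices[k]
        if i1 == i2:
            continue
        a, b = pairs[i1]
        c, d = pairs[i2]
        if flips[k, 0]:
            a, b = b, a
        if flips[k, 1]:
            c, d = d, c
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        old1 = (min(a, b), max(a, b))
        old2 = (min(c, d), max(c, d))
        if new1 == new2:
            continue
        if new1 in occupied and new1 != old1 and new1 != old2:
            continue
        if new2 in occupied and new2 != old1 and new2 != old2:
            continue
        pairs[i1] = new1
        pairs[i2] = new2
        occupied.discard(old1)
        occupied.discard(old2)
        occupied.add(new1)
        occupied.add(new2)


def rewire_layer(layer: LayerMatrix, q: int, seed) -> LayerMatrix:
    """Degree-preserving randomization of one layer.

    Performs ``q * |E|`` attempted pairwise swaps separately on the directed
    arc set and the undirected pair set.  Degree sequences (in/out for
    directed arcs, plain degree for undirected pairs), edge counts and the
    directed/undirected character of every edge are preserved exactly.  The
    same (layer, q, seed) always yields the same result.
    """
    if q <= 0:
        raise ValueError("swap multiplier q must be positive")
    rng = np.random.default_rng(seed)
    arcs = sorted(layer.directed)
    pairs = sorted(layer.undirected)
    occupied = {(min(i, j), max(i, j)) for i, j in arcs} | set(pairs)
    _rewire_directed(arcs, occupied, q * len(arcs), rng)
    _rewire_undirected(pairs, occupied, q * len(pairs), rng)
    return LayerMatrix(layer.label, layer.n, set(arcs), set(pairs))


@dataclass
class RandomEnsemble:
    """Precomputed store of degree-preserving randomized layer instances.

    ``allocate`` maps a (layer pair, context key) to a deterministic,
    collision-free sequence of (instance, instance) index pairs: the k-th
    draw is ((h + k) mod n, ((h + k) div n) mod n) with h a stable CRC32 hash
    of the context.  Consecutive offsets over a window of at most n^2 draws
    are distinct modulo n^2, so the pairs never collide within one context.
    """

    instances: dict = field(default_factory=dict)
    n_instances: int = 0
    q: int = 10
    master_seed: int = 0

    def allocate(
        self, layer_pair: tuple[str, str], n_rand: int, context_key: str
    ) -> list[tuple[int, int]]:
        n = self.n_instances
        if n_rand > n * n:
            raise ValueError(
                f"cannot draw {n_rand} unique instance pairs from {n}x{n} ensemble"
            )
        h = zlib.crc32(f"{layer_pair[0]}|{layer_pair[1]}|{context_key}".encode())
        return [((h + k) % n, ((h + k) // n) % n) for k in range(n_rand)]

    def n_pairings(self) -> int:
        """Unique (instance, instance) pairings available per layer pair."""
        return self.n_instances * self.n_instances


def build_ensemble(
    multilayer: MultilayerNetwork,
    n_instances: int,
    q: int = 10,
    master_seed: int = 0,
    layers: Optional[Iterable[str]] = None,
) -> RandomEnsemble:
    """Randomize every layer of the multiplex ``n_instances`` times.

    Child seeds are spawned per (master_seed, layer position, instance), so
    layers are randomized independently and the whole ensemble is a pure
    function of the master seed.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    labels = list(multilayer.layers) if layers is None else list(layers)
    ens = RandomEnsemble(n_instances=n_instances, q=q, master_seed=master_seed)
    all_labels = list(multilayer.layers)
    for label in labels:
        pos = all_labels.index(label)
        layer = multilayer.layers[label]
        ens.instances[label] = [
            rewire_layer(layer, q, np.random.SeedSequence([master_seed, pos, k]))
            for k in range(n_instances)
        ]
    return ens
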