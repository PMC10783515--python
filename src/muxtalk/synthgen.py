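"""Synthetic multilayer networks, KGML fixtures and benchmark labels.

The generator emulates the statistical structure of the real inputs at toy
scale: sparse, connected pathway subgraphs with typed directed/undirected
edges and partial overlap between adjacent pathways; a denser undirected PPI
scaffold as an Erdos-Renyi graph; and a directed bipartite TF -> target
regulatory layer with a fixed 10% of genes designated TFs.  Every generator
is a pure function of its spec and seed.  Planting routines add coincident
signaling/regulatory edges between two pathways' exclusive node sets (or
through fresh intermediary nodes) to create ground-truth crosstalk for power
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .benchmark import BenchmarkLabels
from .crosstalk import exclusive_nodes
from .netbuild import (
    DEFAULT_TYPE_INDEX,
    GRN_LABEL,
    KEGGPPI_LABEL,
    LAYER_LABELS,
    PPI,
    UNDIRECTED_TYPES,
    EdgeRecord,
    MultilayerNetwork,
    SignalingMultigraph,
    build_multilayer,
    refine_signaling,
)

__all__ = [
    "SynthSpec",
    "PlantSpec",
    "SynthesisError",
    "gen_multilayer",
    "gen_signaling_scene",
    "plant_crosstalk",
    "gen_kgml_fixture",
    "gen_labels",
    "write_fixture_bundle",
]


class SynthesisError(ValueError):
    """Raised for infeasible synthetic-data specifications."""


#: Per-type edge densities (extra typed edges per possible ordered
#: within-pathway position) roughly mirroring the relative abundance of KEGG
#: interaction types: activation and phosphorylation dominate, binding is
#: common, the remaining mechanisms are rare.
DEFAULT_TYPE_DENSITIES: dict[str, float] = {
    "activation": 0.020,
    "binding/association": 0.012,
    "phosphorylation": 0.010,
    "inhibition": 0.008,
    "indirect effect": 0.004,
    "compound": 0.003,
    "dephosphorylation": 0.003,
    "dissociation": 0.003,
    "state change": 0.002,
    "ubiquitination": 0.002,
}


@dataclass
class SynthSpec:
    """Conditions for one synthetic multilayer network.

    Defaults target a desk-scale study: ~200 genes in ~5 sparse, partially
    overlapping pathways (density well under 0.1, as for real signaling
    pathways), a PPI scaffold at 1% density and a sparse TF->target layer.
    """

    n_genes: int = 200
    n_pathways: int = 5
    pathway_size_range: tuple[int, int] = (14, 26)
    type_densities: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_DENSITIES))
    ppi_density: float = 0.01
    grn_density: float = 0.01
    overlap_fraction: float = 0.15
    tf_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.pathway_size_range[0] < 2:
            raise SynthesisError("pathway sizes must be >= 2")
        for name, d in list(self.type_densities.items()) + [
            ("ppi", self.ppi_density),
            ("grn", self.grn_density),
        ]:
            if not 0.0 <= d <= 1.0:
                raise SynthesisError(f"density out of [0, 1] for {name!r}: {d}")


@dataclass
class PlantSpec:
    """A planted crosstalk signal between one ordered pathway pair."""

    pair: tuple[str, str]
    mode: str = "between"  # "between" | "shortest"
    n_planted: int = 5
    multilink_type: tuple[int, int] = (9, 1)
    seed: int = 0


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def gen_signaling_scene(spec: SynthSpec):
    """Generate (multigraph, ppi edges, grn edges, membership) from a spec.

    Pathway subgraphs are random recursive trees (guaranteeing connectedness)
    plus extra typed edges drawn per-type at the requested densities;
    adjacent pathways share ``ceil(overlap_fraction * size)`` genes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    lo, hi = spec.pathway_size_range

    unused = list(genes)
    membership: dict[str, list[str]] = {}
    prev_members: list[str] = []
    for p in range(spec.n_pathways):
        pid = f"path{p:02d}"
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        if prev_members:
            n_shared = min(int(np.ceil(spec.overlap_fraction * size)), len(prev_members))
            shared = rng.choice(len(prev_members), size=n_shared, replace=False)
            members.extend(prev_members[i] for i in sorted(shared))
        need = size - len(members)
        if need > len(unused):
            raise SynthesisError("gene pool exhausted: raise n_genes or shrink pathways")
        take = rng.choice(len(unused), size=need, replace=False)
        members.extend(unused[i] for i in sorted(take))
        for i in sorted(take, reverse=True):
            unused.pop(i)
        membership[pid] = members
        prev_members = members

    type_names = sorted(spec.type_densities)
    weights = np.array([spec.type_densities[t] for t in type_names], dtype=float)
    if weights.sum() <= 0:
        raise SynthesisError("at least one signaling type density must be positive")
    weights = weights / weights.sum()

    # feasibility: a requested nonzero layer must expect at least one edge,
    # counting both the density-driven extras and the typed tree edges
    total_positions = sum(len(m) * (len(m) - 1) for m in membership.values())
    total_tree = sum(len(m) - 1 for m in membership.values())
    for t, w in zip(type_names, weights):
        d = spec.type_densities[t]
        if d > 0 and d * total_positions + w * total_tree < 1:
            raise SynthesisError(f"density for {t!r} too low to place a single edge")

    edges: list[EdgeRecord] = []
    for pid, members in membership.items():
        m = len(members)
        # random recursive tree: node t attaches to a uniform earlier node
        order = list(rng.permutation(m))
        for t in range(1, m):
            parent = members[order[int(rng.integers(0, t))]]
            child = members[order[t]]
            itype = type_names[int(rng.choice(len(type_names), p=weights))]
            directed = itype not in UNDIRECTED_TYPES
            edges.append(EdgeRecord(parent, child, itype, directed, pid))
        # extra typed edges at the requested per-type densities
        n_positions = m * (m - 1)
        for itype in type_names:
            n_extra = int(round(spec.type_densities[itype] * n_positions))
            directed = itype not in UNDIRECTED_TYPES
            placed = 0
            guard = 0
            while placed < n_extra and guard < 50 * (n_extra + 1):
                guard += 1
                i, j = rng.integers(0, m, size=2)
                if i == j:
                    continue
                edges.append(EdgeRecord(members[int(i)], members[int(j)], itype, directed, pid))
                placed += 1

    nodes = set(genes)
    kinds = {g: "gene" for g in genes}
    multigraph = SignalingMultigraph(nodes=nodes, edges=edges, node_kinds=kinds)

    n = spec.n_genes
    if spec.ppi_density > 0 and spec.ppi_density * n * (n - 1) / 2 < 1:
        raise SynthesisError("ppi_density too low to place a single edge")
    ppi_edges: list[tuple[str, str]] = []
    if spec.ppi_density > 0:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < spec.ppi_density
        ppi_edges = [(genes[a], genes[b]) for a, b in zip(iu[mask], ju[mask])]

    tfs = sorted(
        genes[i] for i in rng.choice(n, size=max(1, int(round(spec.tf_fraction * n))), replace=False)
    )
    grn_positions = len(tfs) * (n - 1)
    if spec.grn_density > 0 and spec.grn_density * grn_positions < 1:
        raise SynthesisError("grn_density too low to place a single edge")
    grn_edges: list[tuple[str, str]] = []
    if spec.grn_density > 0:
        for tf in tfs:
            mask = rng.random(n) < spec.grn_density
            for i in np.flatnonzero(mask):
                if genes[i] != tf:
                    grn_edges.append((tf, genes[i]))

    membership_sets = {p: set(m) for p, m in membership.items()}
    return multigraph, ppi_edges, grn_edges, membership_sets, tfs


def gen_multilayer(spec: SynthSpec) -> tuple[MultilayerNetwork, dict]:
    """Generate a complete synthetic multilayer network and pathway membership."""
    multigraph, ppi_edges, grn_edges, membership, _ = gen_signaling_scene(spec)
    refined = refine_signaling(multigraph, ppi_edges)
    net = build_multilayer(refined, grn_edges, membership=membership)
    return net, membership


def _insert_edge(layer, i: int, j: int, directed: bool) -> None:
    """Add an edge keeping each unordered pair singly occupied.

    A directed arc supersedes an undirected edge on the same pair; a
    reciprocal arc collapses the pair to the undirected +1/+1 form; adding
    onto an already-equivalent occupancy is a no-op.
    """
    pair = (min(i, j), max(i, j))
    if directed:
        if pair in layer.undirected or (i, j) in layer.directed:
            return
        if (j, i) in layer.directed:
            layer.directed.discard((j, i))
            layer.undirected.add(pair)
        else:
            layer.directed.add((i, j))
    else:
        if pair in layer.undirected:
            return
        if (i, j) in layer.directed or (j, i) in layer.directed:
            return  # typed directed representation wins
        layer.undirected.add(pair)
    layer.invalidate_cache()


def _add_sig_edge(net: MultilayerNetwork, s: int, i: int, j: int, directed: bool) -> None:
    """Insert a typed signaling edge into layer S and the KEGGPPI layer.

    PPI edges (S = 9) belong to every interaction-specific layer, since each
    typed layer carries the PPI edges for a larger rewiring space.
    """
    targets = list(LAYER_LABELS.values()) if s == 9 else [LAYER_LABELS[s]]
    for label in targets:
        _insert_edge(net.layers[label], i, j, directed)
    _insert_edge(net.layers[KEGGPPI_LABEL], i, j, directed)


def plant_crosstalk(
    multilayer: MultilayerNetwork,
    membership: Mapping[str, set],
    plant: PlantSpec,
) -> tuple[MultilayerNetwork, tuple[tuple[str, str], int]]:
    """Plant coincident signaling + regulatory edges realizing one crosstalk.

    ``between`` mode adds ``n_planted`` (signaling type S, GRN direction R)
    edge pairs on unoccupied positions between the exclusive node sets of the
    pair.  ``shortest`` mode adds fresh intermediary genes x with signaling
    edges a->x and x->b plus GRN edges realizing (S, R) on those positions.
    Returns the modified network and a positive truth label for the pair.
    """
    if plant.n_planted < 1:
        raise SynthesisError("n_planted must be >= 1")
    a_id, b_id = plant.pair
    s, r = plant.multilink_type
    if not (1 <= s <= 11) or r not in (-1, 1):
        raise SynthesisError(f"cannot plant multilink type {plant.multilink_type}")
    net = multilayer.copy()
    rng = np.random.default_rng(plant.seed)
    ex_a, ex_b, _ = exclusive_nodes(a_id, b_id, membership)
    # locality: endpoints must be private to the pair -- a node shared with a
    # third pathway would leak the planted signal into that pathway's
    # between-subsets
    others = set()
    for pid, genes in membership.items():
        if pid not in (a_id, b_id):
            others |= set(genes)
    ex_a -= others
    ex_b -= others
    idx = net.gene_index
    ia = sorted(idx[g] for g in ex_a if g in idx)
    ib = sorted(idx[g] for g in ex_b if g in idx)
    if not ia or not ib:
        raise SynthesisError("insufficient exclusive nodes for planting")
    label = LAYER_LABELS[s]
    directed_type = label not in UNDIRECTED_TYPES
    grn = net.layers[GRN_LABEL]

    if plant.mode == "between":
        occupied = net.layers[label].edge_pairs() | grn.edge_pairs()
        candidates = [
            (i, j)
            for i in ia
            for j in ib
            if (min(i, j), max(i, j)) not in occupied
        ]
        if len(candidates) < plant.n_planted:
            raise SynthesisError("insufficient exclusive nodes for planting")
        picks = rng.choice(len(candidates), size=plant.n_planted, replace=False)
        for p in sorted(picks):
            i, j = candidates[int(p)]
            _add_sig_edge(net, s, i, j, directed_type)
            if r == 1:
                grn.directed.add((i, j))
            else:
                grn.directed.add((j, i))
            grn.invalidate_cache()
    elif plant.mode == "shortest":
        fresh = [f"x_{a_id}_{b_id}_{k:03d}" for k in range(plant.n_planted)]
        net.add_genes(fresh)
        grn = net.layers[GRN_LABEL]
        ia_pick = rng.choice(len(ia), size=plant.n_planted, replace=True)
        ib_pick = rng.choice(len(ib), size=plant.n_planted, replace=True)
        for k, gene in enumerate(fresh):
            x = net.gene_index[gene]
            a = ia[int(ia_pick[k])]
            b = ib[int(ib_pick[k])]
            _add_sig_edge(net, s, a, x, directed_type)
            _add_sig_edge(net, s, x, b, directed_type)
            for u, v in ((a, x), (x, b)):
                if r == 1:
                    grn.directed.add((u, v))
                else:
                    grn.directed.add((v, u))
            grn.invalidate_cache()
    else:
        raise SynthesisError(f"unknown planting mode: {plant.mode!r}")
    return net, (plant.pair, 1)


def gen_kgml_fixture(pathway_spec: Mapping) -> str:
    """Emit a KGML document from a declarative pathway description.

    ``pathway_spec`` has keys ``name``, ``entries`` (dicts with id, type and
    either ``name`` or, for groups, ``components``) and ``relations`` (dicts
    with entry1, entry2, and ``subtypes``; an empty subtype list produces a
    relation with no subtype child).
    """
    from lxml import etree

    root = etree.Element("pathway", name=str(pathway_spec.get("name", "synthetic")))
    for entry in pathway_spec.get("entries", []):
        el = etree.SubElement(
            root, "entry", id=str(entry["id"]), type=str(entry.get("type", "gene"))
        )
        if entry.get("type") == "group":
            for cid in entry.get("components", []):
                etree.SubElement(el, "component", id=str(cid))
        else:
            el.set("name", str(entry.get("name", f"n{entry['id']}")))
    for rel in pathway_spec.get("relations", []):
        el = etree.SubElement(
            root,
            "relation",
            entry1=str(rel["entry1"]),
            entry2=str(rel["entry2"]),
            type=str(rel.get("type", "PPrel")),
        )
        for st in rel.get("subtypes", []):
            etree.SubElement(el, "subtype", name=str(st), value="")
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def gen_labels(
    pathways: Sequence[str], positive_pairs: Iterable[tuple[str, str]]
) -> BenchmarkLabels:
    """Truth labels over all ordered pairs of the pathway list."""
    universe = [(a, b) for a in pathways for b in pathways if a != b]
    positives = list(positive_pairs)
    if len(positives) != len(set(positives)):
        raise ValueError("duplicate positive pairs")
    pos = set(positives)
    bad = pos - set(universe)
    if bad:
        raise ValueError(f"positive pairs outside the universe: {sorted(bad)[:3]}")
    labels = {p: (1 if p in pos else 0) for p in universe}
    return BenchmarkLabels(labels=labels, universe=universe)


def _kgml_from_pathway(pid: str, members: Sequence[str], edges: Sequence[EdgeRecord]) -> str:
    entry_id = {g: str(i + 1) for i, g in enumerate(members)}
    relations = []
    for rec in edges:
        if rec.source in entry_id and rec.target in entry_id:
            relations.append(
                {
                    "entry1": entry_id[rec.source],
                    "entry2": entry_id[rec.target],
                    "type": "PPrel",
                    "subtypes": [rec.interaction_type],
                }
            )
    return gen_kgml_fixture(
        {
            "name": pid,
            "entries": [
                {"id": entry_id[g], "type": "gene", "name": g} for g in members
            ],
            "relations": relations,
        }
    )


def write_fixture_bundle(spec: SynthSpec, outdir, positive_pairs=()) -> dict:
    """Write a complete no-download input set for the command-line interface.

    Produces a KGML directory, ppi.tsv, grn.tsv, membership.gmt, labels.tsv,
    receptors.txt and tfs.txt under ``outdir``; returns the paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "kgml").mkdir(parents=True, exist_ok=True)
    multigraph, ppi_edges, grn_edges, membership, tfs = gen_signaling_scene(spec)

    by_pathway: dict[str, list[EdgeRecord]] = {}
    for rec in multigraph.edges:
        if rec.pathway_id is not None:
            by_pathway.setdefault(rec.pathway_id, []).append(rec)
    for pid in sorted(membership):
        doc = _kgml_from_pathway(pid, sorted(membership[pid]), by_pathway.get(pid, []))
        (outdir / "kgml" / f"{pid}.xml").write_text(doc)

    with open(outdir / "ppi.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in ppi_edges:
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "grn.tsv", "w") as fh:
        fh.write("tf\ttarget\n")
        for tf, tg in grn_edges:
            fh.write(f"{tf}\t{tg}\n")
    with open(outdir / "membership.gmt", "w") as fh:
        for pid in sorted(membership):
            genes = "\t".join(sorted(membership[pid]))
            fh.write(f"{pid}\tsynthetic\t{genes}\n")
    labels = gen_labels(sorted(membership), positive_pairs)
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("pathway_a\tpathway_b\tlabel\n")
        for a, b in labels.universe:
            fh.write(f"{a}\t{b}\t{labels.labels[(a, b)]}\n")
    # toy receptor list: one high-out-degree gene per pathway
    rng = np.random.default_rng(spec.seed + 1)
    receptors = sorted(
        {sorted(membership[pid])[int(rng.integers(0, len(membership[pid])))] for pid in membership}
    )
    (outdir / "receptors.txt").write_text("\n".join(receptors) + "\n")
    (outdir / "tfs.txt").write_text("\n".join(tfs) + "\n")
    return {
        "kgml_dir": outdir / "kgml",
        "ppi": outdir / "ppi.tsv",
        "grn": outdir / "grn.tsv",
        "membership": outdir / "membership.gmt",
        "labels": outdir / "labels.tsv",
        "receptors": outdir / "receptors.txt",
        "tfs": outdir / "tfs.txt",
    }
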