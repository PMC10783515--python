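"""Construction of the signaling-regulatory multilayer network.

The signaling layer is assembled from KEGG-style pathway graphs merged into a
directed heterogeneous multigraph, refined against an undirected PPI scaffold,
and finally split into interaction-type-specific signed sparse layers.  A
directed gene regulatory network (GRN) forms the regulatory layer.  All layers
share one gene index (multiplex contract): every gene is present in every
layer, if only as an isolated node.

Sign convention
---------------
Directed edges i->j are stored as +1 at (i, j) and -1 at (j, i); undirected
edges put +1 at both symmetric positions.  This lets the multilink counting
machinery read off the relative direction of overlapping signaling and
regulatory edges directly from the stacked matrices.  Reciprocal directed
edges (i->j and j->i of the same type) collapse to the undirected +1/+1
representation, which keeps all entries in {-1, 0, +1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "KGML_RELATION_TYPES",
    "GEREL_TYPES",
    "UNDIRECTED_TYPES",
    "WITHIN_GROUP",
    "PPI",
    "UNKNOWN",
    "KEGGPPI_LABEL",
    "GRN_LABEL",
    "DEFAULT_TYPE_INDEX",
    "LAYER_LABELS",
    "BuildError",
    "EdgeRecord",
    "PathwayGraph",
    "SignalingMultigraph",
    "LayerMatrix",
    "MultilayerNetwork",
    "merge_pathways",
    "refine_signaling",
    "build_multilayer",
]

# The closed vocabulary of KEGG relation subtypes (KGML 'relation' elements).
KGML_RELATION_TYPES = frozenset(
    {
        "activation",
        "binding/association",
        "compound",
        "dephosphorylation",
        "dissociation",
        "expression",
        "indirect effect",
        "inhibition",
        "phosphorylation",
        "repression",
        "state change",
        "ubiquitination",
    }
)

WITHIN_GROUP = "within_group"
PPI = "ppi"
UNKNOWN = "unknown"
KEGGPPI_LABEL = "KEGGPPI"
GRN_LABEL = "GRN"

#: GErel (gene-expression relation) subtypes; removed from the signaling layer
#: because transcriptional regulation lives in the dedicated GRN layer.
GEREL_TYPES = frozenset({"expression", "repression"})

#: Relation subtypes without an intrinsic direction; stored once and expanded
#: to the symmetric +1/+1 fill at matrix time.
UNDIRECTED_TYPES = frozenset({"binding/association", "dissociation", WITHIN_GROUP, PPI})

#: Default assignment of interaction types to signaling layer indices S in
#: [1, 11].  ``within_group`` (complete graphs standing in for protein
#: complexes) is folded into binding/association: group co-membership is a
#: physical-association statement.
DEFAULT_TYPE_INDEX: dict[str, int] = {
    "activation": 1,
    "binding/association": 2,
    WITHIN_GROUP: 2,
    "compound": 3,
    "dephosphorylation": 4,
    "dissociation": 5,
    "indirect effect": 6,
    "inhibition": 7,
    "phosphorylation": 8,
    PPI: 9,
    "state change": 10,
    "ubiquitination": 11,
}

#: Canonical layer label for each signaling index S.
LAYER_LABELS: dict[int, str] = {
    1: "activation",
    2: "binding/association",
    3: "compound",
    4: "dephosphorylation",
    5: "dissociation",
    6: "indirect effect",
    7: "inhibition",
    8: "phosphorylation",
    9: PPI,
    10: "state change",
    11: "ubiquitination",
}


class BuildError(ValueError):
    """Raised when multilayer network construction is impossible."""


@dataclass(frozen=True)
class EdgeRecord:
    """One annotated signaling edge.

    ``pathway_id`` is ``None`` for PPI records, which carry no pathway
    context.  Undirected records are stored once; expansion to the
    bidirectional representation happens at matrix-fill time.
    """

    source: str
    target: str
    interaction_type: str
    directed: bool
    pathway_id: Optional[str] = None

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair."""
        a, b = self.source, self.target
        return (a, b) if a <= b else (b, a)


@dataclass
class PathwayGraph:
    """Directed graph parsed from a single KGML pathway definition.

    ``node_kinds`` maps each node identifier to its entry kind (gene,
    compound, map or ortholog); group entries have already been disaggregated
    into within-group complete graphs and do not appear as nodes.
    """

    pathway_id: str
    node_kinds: dict[str, str]
    edges: list[EdgeRecord] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.node_kinds)


@dataclass
class SignalingMultigraph:
    """Heterogeneous directed multigraph aggregating many pathways.

    Parallel edges between the same ordered node pair are allowed and expected:
    the same interaction may be annotated in several pathways, possibly with
    conflicting types (e.g. inhibition in one pathway, activation in another).
    """

    nodes: set[str]
    edges: list[EdgeRecord]
    node_kinds: dict[str, str] = field(default_factory=dict)

    def kind(self, node: str) -> str:
        return self.node_kinds.get(node, "gene")

    def multiplicity_report(self) -> dict[str, float]:
        """Edge multiplicity statistics over pathway-annotated records.

        Returns the fraction of unique node pairs carried by more than one
        pathway and the fraction whose records disagree on interaction type.
        """
        pathways: dict[tuple[str, str], set] = {}
        types: dict[tuple[str, str], set] = {}
        for rec in self.edges:
            if rec.pathway_id is None:
                continue
            pathways.setdefault(rec.pair, set()).add(rec.pathway_id)
            types.setdefault(rec.pair, set()).add(rec.interaction_type)
        n_pairs = len(pathways)
        if n_pairs == 0:
            return {"n_pairs": 0, "frac_multi_pathway": 0.0, "frac_conflicting_type": 0.0}
        multi = sum(1 for s in pathways.values() if len(s) > 1)
        conflict = sum(1 for s in types.values() if len(s) > 1)
        return {
            "n_pairs": n_pairs,
            "frac_multi_pathway": multi / n_pairs,
            "frac_conflicting_type": conflict / n_pairs,
        }


@dataclass
class LayerMatrix:
    """One layer of the multiplex: a signed sparse adjacency over N genes.

    Edges are held as explicit sets -- ``directed`` arcs (i, j) and
    ``undirected`` pairs (i, j) with i < j -- from which the signed matrix is
    materialized on demand.  The sets are the source of truth; rewiring and
    counting operate on them directly.
    """

    label: str
    n: int
    directed: set = field(default_factory=set)
    undirected: set = field(default_factory=set)
    _matrix: Optional[sp.csr_matrix] = field(default=None, repr=False, compare=False)
    _pairs: Optional[frozenset] = field(default=None, repr=False, compare=False)

    def invalidate_cache(self) -> None:
        """Call after mutating the edge sets in place."""
        self._matrix = None
        self._pairs = None

    @classmethod
    def from_edges(
        cls,
        label: str,
        n: int,
        arcs: Iterable[tuple[int, int]] = (),
        undirected_pairs: Iterable[tuple[int, int]] = (),
        undirected_wins: bool = False,
    ) -> "LayerMatrix":
        """Normalize raw edge input into the signed representation.

        Per unordered pair: reciprocal directed arcs collapse to the
        undirected +1/+1 fill; a single directed arc wins over a coincident
        undirected edge (the typed signed representation supersedes, e.g. a
        directed KEGG edge over a PPI edge on the same pair) unless
        ``undirected_wins`` is set, in which case any undirected presence
        makes the pair bidirectional (used for the collapsed KEGGPPI layer,
        where an undirected edge genuinely connects both ways).
        """
        fwd: set = set()
        und: set = set()
        for i, j in arcs:
            if i != j:
                fwd.add((int(i), int(j)))
        for i, j in undirected_pairs:
            if i != j:
                und.add((min(int(i), int(j)), max(int(i), int(j))))
        directed_out: set = set()
        undirected_out: set = set()
        seen: set = set()
        for i, j in fwd:
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            recip = (j, i) in fwd
            has_und = key in und
            if recip or (has_und and undirected_wins):
                undirected_out.add(key)
            else:
                directed_out.add((i, j))
        for key in und:
            if key not in seen:
                undirected_out.add(key)
        return cls(label=label, n=n, directed=directed_out, undirected=undirected_out)

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def edge_pairs(self) -> frozenset:
        """All occupied unordered pairs (cached)."""
        if self._pairs is None:
            pairs = {(min(i, j), max(i, j)) for i, j in self.directed}
            pairs |= self.undirected
            self._pairs = frozenset(pairs)
        return self._pairs

    @property
    def matrix(self) -> sp.csr_matrix:
        """Signed adjacency: +1/-1 per directed arc, +1/+1 per undirected pair."""
        if self._matrix is None:
            rows, cols, vals = [], [], []
            for i, j in self.directed:
                rows += [i, j]
                cols += [j, i]
                vals += [1, -1]
            for i, j in self.undirected:
                rows += [i, j]
                cols += [j, i]
                vals += [1, 1]
            self._matrix = sp.csr_matrix(
                (np.asarray(vals, dtype=np.int8), (rows, cols)), shape=(self.n, self.n)
            )
        return self._matrix

    def degree_sequences(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(out-degree, in-degree, undirected degree) vectors."""
        dout = np.zeros(self.n, dtype=int)
        din = np.zeros(self.n, dtype=int)
        dund = np.zeros(self.n, dtype=int)
        for i, j in self.directed:
            dout[i] += 1
            din[j] += 1
        for i, j in self.undirected:
            dund[i] += 1
            dund[j] += 1
        return dout, din, dund

    def copy(self) -> "LayerMatrix":
        return LayerMatrix(self.label, self.n, set(self.directed), set(self.undirected))

    def with_n(self, n: int) -> "LayerMatrix":
        """Same edges over an enlarged node universe."""
        if n < self.n:
            raise ValueError("cannot shrink a layer")
        return LayerMatrix(self.label, n, set(self.directed), set(self.undirected))


@dataclass
class MultilayerNetwork:
    """The full multiplex: 11 typed signaling layers + KEGGPPI + GRN.

    All layers share ``gene_index``; ``pathway_members`` maps pathway ids to
    gene-id sets restricted to the universe.
    """

    genes: list[str]
    gene_index: dict[str, int]
    layers: dict[str, LayerMatrix]
    type_index: dict[str, int]
    pathway_members: dict[str, set] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def signaling_labels(self) -> list[str]:
        """Labels of the 11 interaction-specific layers, ordered by S."""
        return [LAYER_LABELS[s] for s in sorted(LAYER_LABELS)]

    def layer_for_s(self, s: int) -> LayerMatrix:
        if s == 0:
            return self.layers[KEGGPPI_LABEL]
        return self.layers[LAYER_LABELS[s]]

    @property
    def grn(self) -> LayerMatrix:
        return self.layers[GRN_LABEL]

    @property
    def keggppi(self) -> LayerMatrix:
        return self.layers[KEGGPPI_LABEL]

    def member_indices(self, pathway_id: str) -> set:
        try:
            members = self.pathway_members[pathway_id]
        except KeyError:
            raise KeyError(f"unknown pathway id: {pathway_id!r}")
        return {self.gene_index[g] for g in members if g in self.gene_index}

    def copy(self) -> "MultilayerNetwork":
        return MultilayerNetwork(
            genes=list(self.genes),
            gene_index=dict(self.gene_index),
            layers={lab: lay.copy() for lab, lay in self.layers.items()},
            type_index=dict(self.type_index),
            pathway_members={p: set(m) for p, m in self.pathway_members.items()},
        )

    def add_genes(self, new_genes: Sequence[str]) -> None:
        """Extend the shared gene universe (all layers grow in lock-step)."""
        for g in new_genes:
            if g in self.gene_index:
                raise ValueError(f"gene already present: {g!r}")
            self.gene_index[g] = len(self.genes)
            self.genes.append(g)
        n = len(self.genes)
        for lab in self.layers:
            self.layers[lab] = self.layers[lab].with_n(n)


def merge_pathways(pathway_graphs: Sequence[PathwayGraph]) -> SignalingMultigraph:
    """Aggregate pathway graphs into one directed heterogeneous multigraph.

    Per-edge (interaction_type, pathway_id) annotations are preserved;
    identical edges contributed by different pathways remain distinct records.
    """
    if not pathway_graphs:
        raise ValueError("merge_pathways requires at least one pathway graph")
    nodes: set = set()
    kinds: dict[str, str] = {}
    edges: list[EdgeRecord] = []
    for pg in pathway_graphs:
        nodes |= pg.nodes
        for node, kind in pg.node_kinds.items():
            kinds.setdefault(node, kind)
        edges.extend(pg.edges)
    return SignalingMultigraph(nodes=nodes, edges=edges, node_kinds=kinds)


def refine_signaling(
    multigraph: SignalingMultigraph,
    ppi_edges: Iterable[tuple[str, str]],
) -> SignalingMultigraph:
    """Quality-control the signaling multigraph and merge in the PPI scaffold.

    In order: (a) drop non-gene nodes (compounds, maps, orthologs) and their
    edges; (b) drop unknown-type records; (c) drop self-loops; (d) drop GErel
    (expression/repression) records, which are redundant with the GRN layer;
    (e) add each PPI edge as an undirected ``ppi`` record only if the
    unordered pair is not already covered by any retained record (a known
    signaling interaction supersedes the PPI edge).  Idempotent for a fixed
    PPI list.
    """
    gene_nodes = {n for n in multigraph.nodes if multigraph.kind(n) == "gene"}
    kept: list[EdgeRecord] = []
    covered: set = set()
    for rec in multigraph.edges:
        if rec.source not in gene_nodes or rec.target not in gene_nodes:
            continue
        if rec.interaction_type == UNKNOWN:
            continue
        if rec.source == rec.target:
            continue
        if rec.interaction_type in GEREL_TYPES:
            continue
        kept.append(rec)
        covered.add(rec.pair)
    nodes = set(gene_nodes)
    for a, b in ppi_edges:
        if a == b:
            continue
        nodes.add(a)
        nodes.add(b)
        pair = (a, b) if a <= b else (b, a)
        if pair in covered:
            continue
        covered.add(pair)
        kept.append(EdgeRecord(pair[0], pair[1], PPI, directed=False, pathway_id=None))
    kinds = {n: "gene" for n in nodes}
    return SignalingMultigraph(nodes=nodes, edges=kept, node_kinds=kinds)


def build_multilayer(
    signaling: SignalingMultigraph,
    grn_edges: Iterable[tuple[str, str]],
    type_index: Optional[Mapping[str, int]] = None,
    membership: Optional[Mapping[str, set]] = None,
) -> MultilayerNetwork:
    """Assemble the 13-layer multiplex from a refined signaling multigraph.

    Each interaction-specific layer S holds all type-S edges plus every PPI
    edge (enlarging the rewiring space); the KEGGPPI layer collapses every
    signaling/PPI edge once without type distinction; the GRN layer is pruned
    to the signaling gene universe.
    """
    tindex = dict(DEFAULT_TYPE_INDEX if type_index is None else type_index)
    genes = sorted(signaling.nodes)
    gene_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    arcs_by_s: dict[int, list] = {s: [] for s in LAYER_LABELS}
    und_by_s: dict[int, list] = {s: [] for s in LAYER_LABELS}
    ppi_pairs: list = []
    all_arcs: list = []
    all_und: list = []
    for rec in signaling.edges:
        try:
            s = tindex[rec.interaction_type]
        except KeyError:
            raise BuildError(f"interaction type not in type_index: {rec.interaction_type!r}")
        i, j = gene_index[rec.source], gene_index[rec.target]
        if rec.directed:
            arcs_by_s[s].append((i, j))
            all_arcs.append((i, j))
        else:
            und_by_s[s].append((i, j))
            all_und.append((i, j))
            if rec.interaction_type == PPI:
                ppi_pairs.append((i, j))

    layers: dict[str, LayerMatrix] = {}
    for s in sorted(LAYER_LABELS):
        label = LAYER_LABELS[s]
        layers[label] = LayerMatrix.from_edges(
            label, n, arcs=arcs_by_s[s], undirected_pairs=und_by_s[s] + ppi_pairs
        )
    layers[KEGGPPI_LABEL] = LayerMatrix.from_edges(
        KEGGPPI_LABEL, n, arcs=all_arcs, undirected_pairs=all_und, undirected_wins=True
    )

    grn_arcs = []
    for tf, tg in grn_edges:
        if tf in gene_index and tg in gene_index and tf != tg:
            grn_arcs.append((gene_index[tf], gene_index[tg]))
    if not grn_arcs:
        raise BuildError("empty regulatory layer: no GRN edge maps into the signaling gene universe")
    layers[GRN_LABEL] = LayerMatrix.from_edges(GRN_LABEL, n, arcs=grn_arcs)

    if membership is None:
        members: dict[str, set] = {}
        for rec in signaling.edges:
            if rec.pathway_id is None:
                continue
            members.setdefault(rec.pathway_id, set()).update((rec.source, rec.target))
    else:
        members = {p: set(m) & set(genes) for p, m in membership.items()}

    return MultilayerNetwork(
        genes=genes,
        gene_index=gene_index,
        layers=layers,
        type_index=tindex,
        pathway_members=members,
    )
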