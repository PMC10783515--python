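"""KGML (KEGG Markup Language) parsing.

A KGML document describes one pathway as ``entry`` elements (nodes: genes,
compounds, maps, orthologs, or groups of entries) and ``relation`` elements
(typed edges between entries).  Parsing yields a :class:`PathwayGraph` whose
edges carry the relation subtype, directedness, and pathway id.

Dialect choices: an entry's ``name`` attribute may list several identifiers
(whitespace-separated); a relation between multi-identifier entries expands to
the Cartesian product of endpoint identifiers.  A relation with several
subtype children yields one edge record per subtype.  Group entries are
disaggregated into complete graphs of their member genes, annotated
``within_group`` and undirected.  Subtypes outside the closed KEGG vocabulary
are flagged ``unknown`` and dropped downstream during refinement.
"""

from __future__ import annotations

from itertools import combinations, product
from os import PathLike
from typing import Union

from lxml import etree

from .netbuild import (
    KGML_RELATION_TYPES,
    UNDIRECTED_TYPES,
    UNKNOWN,
    WITHIN_GROUP,
    EdgeRecord,
    PathwayGraph,
)

__all__ = ["KGMLParseError", "KGMLStructureError", "parse_kgml"]

#: Entry kinds retained as typed nodes at parse time (non-gene kinds are
#: removed later, during signaling-layer refinement).
_ENTRY_KINDS = {"gene": "gene", "compound": "compound", "map": "map", "ortholog": "ortholog"}


class KGMLParseError(ValueError):
    """Malformed KGML XML."""


class KGMLStructureError(ValueError):
    """Structurally invalid KGML (e.g. a relation names an undeclared entry)."""


def _load_root(document: Union[str, bytes, PathLike]):
    if isinstance(document, bytes):
        text = document
    elif isinstance(document, str) and document.lstrip().startswith("<"):
        text = document.encode()
    else:
        try:
            with open(document, "rb") as fh:
                text = fh.read()
        except OSError as exc:
            raise KGMLParseError(f"cannot read KGML document: {exc}") from exc
    try:
        # KGML ships a DTD reference; do not attempt to resolve it.
        parser = etree.XMLParser(load_dtd=False, no_network=True, resolve_entities=False)
        return etree.fromstring(text, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed KGML XML: {exc}") from exc


def parse_kgml(document: Union[str, bytes, PathLike]) -> PathwayGraph:
    """Parse one KGML document (path, XML string, or bytes) into a PathwayGraph.

    Raises :class:`KGMLParseError` on malformed XML and
    :class:`KGMLStructureError` when a relation references an undeclared
    entry id.
    """
    root = _load_root(document)
    pathway_id = root.get("name") or root.get("title") or "pathway"

    entry_names: dict[str, list[str]] = {}
    entry_kind: dict[str, str] = {}
    group_components: dict[str, list[str]] = {}
    node_kinds: dict[str, str] = {}

    for entry in root.findall("entry"):
        eid = entry.get("id")
        kind = entry.get("type", "gene")
        if kind == "group":
            group_components[eid] = [c.get("id") for c in entry.findall("component")]
            entry_kind[eid] = "group"
            continue
        names = (entry.get("name") or "").split()
        entry_names[eid] = names
        entry_kind[eid] = kind
        node_kind = _ENTRY_KINDS.get(kind, kind)
        for name in names:
            node_kinds.setdefault(name, node_kind)

    def resolve(eid: str) -> list[str]:
        """Identifier list for an entry, expanding groups to member names."""
        if eid in group_components:
            names: list[str] = []
            for cid in group_components[eid]:
                if cid not in entry_names:
                    raise KGMLStructureError(
                        f"group entry {eid!r} references undeclared entry id {cid!r}"
                    )
                names.extend(entry_names[cid])
            return names
        if eid not in entry_names:
            raise KGMLStructureError(f"relation references undeclared entry id {eid!r}")
        return entry_names[eid]

    edges: list[EdgeRecord] = []

    # Disaggregate groups: complete graph over member genes, undirected.
    for gid, comps in group_components.items():
        members: list[str] = []
        for cid in comps:
            if cid not in entry_names:
                raise KGMLStructureError(
                    f"group entry {gid!r} references undeclared entry id {cid!r}"
                )
            members.extend(entry_names[cid])
        for a, b in combinations(dict.fromkeys(members), 2):
            edges.append(EdgeRecord(a, b, WITHIN_GROUP, directed=False, pathway_id=pathway_id))

    for relation in root.findall("relation"):
        src = relation.get("entry1")
        tgt = relation.get("entry2")
        src_names = resolve(src)
        tgt_names = resolve(tgt)
        subtypes = [st.get("name") for st in relation.findall("subtype")]
        if not subtypes:
            subtypes = [None]
        for name in subtypes:
            itype = name if name in KGML_RELATION_TYPES else UNKNOWN
            directed = itype not in UNDIRECTED_TYPES
            for a, b in product(src_names, tgt_names):
                edges.append(
                    EdgeRecord(a, b, itype, directed=directed, pathway_id=pathway_id)
                )

    return PathwayGraph(pathway_id=pathway_id, node_kinds=node_kinds, edges=edges)
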