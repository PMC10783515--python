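"""Readers/writers for edge tables, GMT membership, labels and npz bundles."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .benchmark import BenchmarkLabels
from .netbuild import EdgeRecord, LayerMatrix, MultilayerNetwork, SignalingMultigraph
from .randomize import RandomEnsemble

__all__ = [
    "read_ppi_tsv",
    "read_grn_tsv",
    "read_gmt",
    "write_gmt",
    "read_labels_tsv",
    "read_gene_list",
    "write_multigraph_tsv",
    "read_multigraph_tsv",
    "save_multilayer",
    "load_multilayer",
    "save_ensemble",
    "load_ensemble",
]


def _read_weighted_pairs(path, col_a, col_b, min_weight: Optional[float]) -> list:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(frame.columns)
    if col_a not in cols or col_b not in cols:
        # headerless two/three-column file
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
        frame.columns = ([col_a, col_b] + [f"w{i}" for i in range(len(frame.columns) - 2)])
    if min_weight is not None:
        weight_cols = [c for c in frame.columns if c not in (col_a, col_b)]
        if not weight_cols:
            raise ValueError("min_weight given but the edge table has no weight column")
        w = pd.to_numeric(frame[weight_cols[0]])
        frame = frame[w >= min_weight]
    return list(zip(frame[col_a], frame[col_b]))


def read_ppi_tsv(path, min_weight: Optional[float] = None) -> list:
    """Undirected PPI edge list (columns gene_a, gene_b [, weight])."""
    return _read_weighted_pairs(path, "gene_a", "gene_b", min_weight)


def read_grn_tsv(path, min_weight: Optional[float] = None) -> list:
    """Directed TF -> target edge list (columns tf, target [, weight])."""
    return _read_weighted_pairs(path, "tf", "target", min_weight)


def read_gmt(path) -> dict:
    """Pathway membership from GMT (name, description, genes...)."""
    members: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            members[parts[0]] = set(parts[2:])
    return members


def write_gmt(membership, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(membership):
            fh.write(pid + "\t-\t" + "\t".join(sorted(membership[pid])) + "\n")


def read_labels_tsv(path) -> BenchmarkLabels:
    """Benchmark labels (columns pathway_a, pathway_b, label in {0, 1})."""
    frame = pd.read_csv(path, sep="\t", dtype={"pathway_a": str, "pathway_b": str})
    labels = {}
    universe = []
    for row in frame.itertuples(index=False):
        pair = (row.pathway_a, row.pathway_b)
        universe.append(pair)
        labels[pair] = int(row.label)
    return BenchmarkLabels(labels=labels, universe=universe)


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_multigraph_tsv(multigraph: SignalingMultigraph, path) -> None:
    """Multigraph edge table: source, target, type, directed, pathway."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\ttype\tdirected\tpathway\n")
        for rec in multigraph.edges:
            pw = "" if rec.pathway_id is None else rec.pathway_id
            fh.write(
                f"{rec.source}\t{rec.target}\t{rec.interaction_type}\t"
                f"{int(rec.directed)}\t{pw}\n"
            )


def read_multigraph_tsv(path) -> SignalingMultigraph:
    """Inverse of :func:`write_multigraph_tsv` (exact round trip)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    edges = [
        EdgeRecord(
            row.source,
            row.target,
            row.type,
            bool(int(row.directed)),
            row.pathway or None,
        )
        for row in frame.itertuples(index=False)
    ]
    nodes = {e.source for e in edges} | {e.target for e in edges}
    return SignalingMultigraph(nodes=nodes, edges=edges, node_kinds={n: "gene" for n in nodes})


def _layer_arrays(layer: LayerMatrix) -> dict:
    d = np.asarray(sorted(layer.directed), dtype=np.int64).reshape(-1, 2)
    u = np.asarray(sorted(layer.undirected), dtype=np.int64).reshape(-1, 2)
    return {"directed": d, "undirected": u}


def save_multilayer(net: MultilayerNetwork, path) -> None:
    """Serialize the multilayer bundle as npz arrays + JSON metadata."""
    arrays: dict[str, np.ndarray] = {"genes": np.asarray(net.genes, dtype=object)}
    meta = {
        "layers": list(net.layers),
        "type_index": net.type_index,
        "pathway_members": {p: sorted(m) for p, m in net.pathway_members.items()},
        "n": net.n,
    }
    for k, (label, layer) in enumerate(net.layers.items()):
        la = _layer_arrays(layer)
        arrays[f"layer{k}_directed"] = la["directed"]
        arrays[f"layer{k}_undirected"] = la["undirected"]
    arrays["meta"] = np.asarray(json.dumps(meta))
    np.savez_compressed(path, **arrays, allow_pickle=True)


def load_multilayer(path) -> MultilayerNetwork:
    with np.load(path, allow_pickle=True) as data:
        meta = json.loads(str(data["meta"]))
        genes = [str(g) for g in data["genes"]]
        layers = {}
        for k, label in enumerate(meta["layers"]):
            d = data[f"layer{k}_directed"]
            u = data[f"layer{k}_undirected"]
            layers[label] = LayerMatrix(
                label,
                meta["n"],
                {(int(i), int(j)) for i, j in d},
                {(int(i), int(j)) for i, j in u},
            )
    return MultilayerNetwork(
        genes=genes,
        gene_index={g: i for i, g in enumerate(genes)},
        layers=layers,
        type_index={k: int(v) for k, v in meta["type_index"].items()},
        pathway_members={p: set(m) for p, m in meta["pathway_members"].items()},
    )


def save_ensemble(ens: RandomEnsemble, path) -> None:
    """Serialize a randomized-instance store (npz arrays + JSON manifest)."""
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "labels": list(ens.instances),
        "n_instances": ens.n_instances,
        "q": ens.q,
        "master_seed": ens.master_seed,
        "n": {label: insts[0].n for label, insts in ens.instances.items()},
    }
    for label, insts in ens.instances.items():
        for k, layer in enumerate(insts):
            la = _layer_arrays(layer)
            arrays[f"{label}__{k}__d"] = la["directed"]
            arrays[f"{label}__{k}__u"] = la["undirected"]
    arrays["meta"] = np.asarray(json.dumps(meta))
    np.savez_compressed(path, **arrays, allow_pickle=True)


def load_ensemble(path) -> RandomEnsemble:
    with np.load(path, allow_pickle=True) as data:
        meta = json.loads(str(data["meta"]))
        ens = RandomEnsemble(
            n_instances=meta["n_instances"], q=meta["q"], master_seed=meta["master_seed"]
        )
        for label in meta["labels"]:
            insts = []
            for k in range(meta["n_instances"]):
                d = data[f"{label}__{k}__d"]
                u = data[f"{label}__{k}__u"]
                insts.append(
                    LayerMatrix(
                        label,
                        meta["n"][label],
                        {(int(i), int(j)) for i, j in d},
                        {(int(i), int(j)) for i, j in u},
                    )
                )
            ens.instances[label] = insts
    return ens
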