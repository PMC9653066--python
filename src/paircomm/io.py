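"""Readers and writers for the table, tree and graph formats the pipeline touches.

Counts travel as TSV (taxa rows, samples columns) plus a sample-metadata TSV,
or as BIOM v1 (JSON dialect).  Trees are Newick via scikit-bio.  Networks are
exported as GraphML or an edge-list TSV carrying r, adjusted p and sign.
Readers validate and reject malformed input instead of coercing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CountMatrix, FunctionTable

__all__ = [
    "read_counts",
    "write_counts",
    "read_function_table",
    "write_function_table",
    "read_newick",
    "write_newick",
    "write_graph",
    "read_graph",
]


def _read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in md.columns:
        raise ValueError(f"{path}: metadata must have a 'sample_id' column")
    for col in ("group", "pair"):
        if col not in md.columns:
            raise ValueError(f"{path}: metadata must have a {col!r} column")
    return md.set_index("sample_id")


def read_counts(path, metadata_path=None, format="tsv") -> CountMatrix:
    """Read a count table, validating counts and metadata.

    ``format='tsv'`` expects taxa rows with a header of sample ids and a
    separate metadata TSV (columns sample_id, group, pair).  ``format='biom'``
    expects a BIOM v1 JSON file with group/pair in the column metadata;
    an external metadata TSV, when given, overrides it.
    """
    path = Path(path)
    if format == "tsv":
        if metadata_path is None:
            raise ValueError("TSV counts require a metadata_path")
        df = pd.read_csv(path, sep="\t", index_col=0)
        num = df.apply(pd.to_numeric, errors="coerce")
        if num.isna().any().any():
            r, c = np.argwhere(num.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: non-numeric count at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            )
        if (num < 0).any().any():
            r, c = np.argwhere((num < 0).to_numpy())[0]
            raise ValueError(
                f"{path}: negative count at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            )
        md = _read_metadata(metadata_path)
        return CountMatrix(list(df.index), list(df.columns), num.to_numpy(), md)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") not in {"sparse", "dense"}:
            raise ValueError(f"{path}: unsupported BIOM matrix_type")
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape)
        if doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"])
        if metadata_path is not None:
            md = _read_metadata(metadata_path)
        else:
            recs = {}
            for c in doc["columns"]:
                cmd = c.get("metadata") or {}
                recs[c["id"]] = {"group": cmd.get("group"), "pair": cmd.get("pair")}
            md = pd.DataFrame.from_dict(recs, orient="index")
        return CountMatrix(taxa, samples, mat, md)
    raise ValueError(f"unknown counts format {format!r}")


def write_counts(cm: CountMatrix, path, metadata_path=None, format="tsv") -> None:
    path = Path(path)
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t")
        if metadata_path is not None:
            md = cm.metadata[["group", "pair"]].copy()
            md.index.name = "sample_id"
            md.to_csv(metadata_path, sep="\t")
        return
    if format == "biom":
        rows = [{"id": t, "metadata": None} for t in cm.taxon_ids]
        cols = [
            {
                "id": s,
                "metadata": {
                    "group": str(cm.metadata.loc[s, "group"]),
                    "pair": str(cm.metadata.loc[s, "pair"]),
                },
            }
            for s in cm.sample_ids
        ]
        data = [
            [int(i), int(j), int(cm.counts[i, j])]
            for i, j in zip(*np.nonzero(cm.counts))
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "paircomm",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [cm.n_taxa, cm.n_samples],
            "rows": rows,
            "columns": cols,
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown counts format {format!r}")


def read_function_table(path) -> FunctionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return FunctionTable(list(df.index), list(df.columns), num.to_numpy())


def write_function_table(table: FunctionTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_newick(path) -> TreeNode:
    """Parse a rooted Newick tree, checking balance and leaf uniqueness."""
    text = Path(path).read_text()
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"{path}: unbalanced ')' at position {pos}")
    if depth != 0:
        raise ValueError(f"{path}: {depth} unclosed '(' in Newick string")
    tree = TreeNode.read([text])
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate leaf names in tree")
    for node in tree.traverse():
        if node.length is not None and not np.isfinite(node.length):
            raise ValueError(f"{path}: non-finite branch length at {node.name!r}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


def write_graph(network: nx.Graph, path, format="graphml") -> None:
    """Export a co-occurrence network with per-edge r, adjusted p and sign."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
        return
    if format == "edgelist_tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "r": d.get("r"),
                "p_adjusted": d.get("p_adjusted"),
                "sign": d.get("sign"),
            }
            for u, v, d in network.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "r", "p_adjusted", "sign"]).to_csv(
            path, sep="\t", index=False
        )
        return
    raise ValueError(f"unknown graph format {format!r}")


def read_graph(path) -> nx.Graph:
    return nx.read_graphml(str(path))
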