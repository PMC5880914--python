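"""Readers and writers for the plain-text interchange formats.

On disk an OTU table follows the common amplicon convention of OTUs as rows
and samples as columns; in memory the table is samples x OTUs, so the
readers/writers transpose. A minimal BIOM-1.0-style JSON dialect (dense or
sparse) is supported alongside TSV. Trees are newick, read through dendropy.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import dendropy
import numpy as np
import pandas as pd

from .containers import (
    DistanceMatrix,
    OtuTable,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def read_otu_table(path: PathLike, format: str = "tsv") -> OtuTable:
    """Read an OTU count table from ``tsv`` (OTUs x samples on disk) or
    ``biom-json``; returns a validated samples-x-OTUs :class:`OtuTable`."""
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom-json":
        return _read_otu_biom_json(path)
    raise ValueError(f"unknown OTU table format {format!r}")


def _read_otu_tsv(path: PathLike) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    otu_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    taxonomy = None
    if sample_ids and sample_ids[-1].lower() in ("taxonomy", "lineage"):
        taxonomy = dict(zip(otu_ids, df.iloc[:, -1].astype(str)))
        df = df.iloc[:, :-1]
        sample_ids = sample_ids[:-1]
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric count {raw!r} at OTU {otu_ids[i]}, sample {sample_ids[j]}"
                ) from None
            if val < 0:
                raise ValidationError(
                    f"negative count at OTU {otu_ids[i]}, sample {sample_ids[j]}"
                )
            if val != round(val):
                raise ValidationError(
                    f"non-integral count at OTU {otu_ids[i]}, sample {sample_ids[j]}"
                )
            mat[i, j] = int(round(val))
    # disk layout is OTUs x samples; memory layout samples x OTUs
    return OtuTable(sample_ids, otu_ids, mat.T, taxonomy)


def write_otu_table(table: OtuTable, path: PathLike, format: str = "tsv") -> None:
    if format == "tsv":
        df = pd.DataFrame(table.counts.T, index=table.otu_ids, columns=table.sample_ids)
        df.index.name = "#OTU_ID"
        if table.taxonomy:
            df["taxonomy"] = [table.taxonomy.get(o, "") for o in table.otu_ids]
        df.to_csv(path, sep="\t")
    elif format == "biom-json":
        _write_otu_biom_json(table, path)
    else:
        raise ValueError(f"unknown OTU table format {format!r}")


def _read_otu_biom_json(path: PathLike) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    n_otus, n_samples = doc["shape"]
    mat = np.zeros((n_otus, n_samples))
    if doc.get("matrix_type", "dense") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    if np.any(mat < 0):
        raise ValidationError("negative count in BIOM data")
    if np.any(mat != np.round(mat)):
        raise ValidationError("non-integral count in BIOM data")
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax:
            taxonomy[str(r["id"])] = tax if isinstance(tax, str) else "; ".join(tax)
    return OtuTable(sample_ids, otu_ids, mat.T.astype(np.int64), taxonomy or None)


def _write_otu_biom_json(table: OtuTable, path: PathLike) -> None:
    rows = []
    for o in table.otu_ids:
        md = {"taxonomy": table.taxonomy[o]} if table.taxonomy and o in table.taxonomy else None
        rows.append({"id": o, "metadata": md})
    mat = table.counts.T
    data = [[int(i), int(j), int(mat[i, j])] for i, j in zip(*np.nonzero(mat))]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "elevassembly",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: PathLike) -> SampleMetadata:
    """Tab-separated metadata, one row per sample, first column sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: PathLike) -> None:
    out = metadata.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path: PathLike) -> dendropy.Tree:
    """Rooted newick tree; missing branch lengths default to 0 with a warning."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"newick parse error in {path}: {exc}") from exc
    tree.is_rooted = True
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
    if n_missing:
        logger.warning("%d branches lacked lengths; set to 0", n_missing)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def read_distance_matrix(path: PathLike, kind: str = "dissimilarity") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValidationError("distance matrix header does not match first column")
    return DistanceMatrix(ids, df.to_numpy(dtype=float), kind=kind)


def write_distance_matrix(dm: DistanceMatrix, path: PathLike) -> None:
    dm.to_dataframe().to_csv(path, sep="\t")
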