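"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices travel as 10x-style MatrixMarket bundles (matrix.mtx +
features.tsv + barcodes.tsv + cell_meta.tsv), gene sets as GMT, and result
tables as TSV/JSON.  Orientation of the matrix on disk is inferred by
matching the header dimensions against the features/barcodes lengths, and
ambiguous (square) cases are rejected rather than guessed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dataset import META_COLUMNS, ExpressionDataset, GeneSetCollection, ValidationError


class FormatError(ValueError):
    """Raised for malformed on-disk inputs."""


def _read_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_mtx_bundle(matrix_path, features_path, barcodes_path, meta_path=None) -> ExpressionDataset:
    """Read a MatrixMarket count bundle into an :class:`ExpressionDataset`.

    Genes become rows regardless of the on-disk orientation.  The features
    file may carry one or more tab-separated columns (Cell Ranger writes
    id/symbol/type); only the first column is used as the gene id.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except ValueError as exc:
        raise FormatError(f"cannot parse {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    bad = np.flatnonzero((mat.data < 0) | (mat.data != np.round(mat.data)))
    if bad.size:
        i = bad[0]
        raise FormatError(
            f"negative or non-integer value {mat.data[i]} at "
            f"coordinate ({mat.row[i] + 1}, {mat.col[i] + 1})"
        )
    genes = [line.split("\t")[0] for line in _read_lines(features_path)]
    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]
    if len(set(barcodes)) != len(barcodes):
        raise ValidationError("duplicate barcodes")
    n_rows, n_cols = mat.shape
    if n_rows == n_cols and len(genes) != len(barcodes):
        raise FormatError(
            f"square matrix {n_rows}x{n_cols}: orientation is ambiguous"
        )
    if (n_rows, n_cols) == (len(genes), len(barcodes)):
        pass
    elif (n_rows, n_cols) == (len(barcodes), len(genes)):
        mat = mat.T
    else:
        raise FormatError(
            f"matrix is {n_rows}x{n_cols} but features has {len(genes)} "
            f"records and barcodes has {len(barcodes)}"
        )
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "cell_id" not in meta.columns or "cluster_label" not in meta.columns:
            raise FormatError("metadata TSV must contain cell_id and cluster_label columns")
        meta = meta.set_index("cell_id")
    embedding = None
    emb_path = Path(matrix_path).parent / "embedding.tsv"
    if emb_path.exists():
        emb = pd.read_csv(emb_path, sep="\t").set_index("cell_id")
        embedding = emb.loc[barcodes].to_numpy(dtype=float)
    return ExpressionDataset(
        counts=mat.tocsr().astype(np.int64),
        gene_ids=genes,
        cell_ids=barcodes,
        cell_meta=meta,
        embedding=embedding,
    )


def write_mtx_bundle(dataset: ExpressionDataset, out_dir) -> dict[str, Path]:
    """Write matrix.mtx + features.tsv + barcodes.tsv + cell_meta.tsv."""
    if dataset.n_cells == 0 or dataset.n_genes == 0:
        raise ValidationError("refusing to serialize an empty dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "cell_meta": out / "cell_meta.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(dataset.counts), field="integer")
    paths["features"].write_text("\n".join(dataset.gene_ids) + "\n", encoding="utf-8")
    paths["barcodes"].write_text("\n".join(dataset.cell_ids) + "\n", encoding="utf-8")
    meta = dataset.cell_meta[list(META_COLUMNS)].copy()
    meta.insert(0, "cell_id", meta.index)
    meta.to_csv(paths["cell_meta"], sep="\t", index=False)
    if dataset.embedding is not None:
        emb = pd.DataFrame(
            dataset.embedding,
            columns=[f"dim{i+1}" for i in range(dataset.embedding.shape[1])],
        )
        emb.insert(0, "cell_id", dataset.cell_ids)
        paths["embedding"] = out / "embedding.tsv"
        emb.to_csv(paths["embedding"], sep="\t", index=False)
    return paths


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (name, description, genes...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [line.rstrip("\n") for line in fh]
    n_parsed = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected >= 3 tab-separated fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        # dedupe preserving first occurrence
        seen: dict[str, None] = dict.fromkeys(genes)
        if name in sets:
            raise FormatError(f"line {lineno}: duplicate set name {name!r}")
        sets[name] = (desc, list(seen))
        n_parsed += 1
    if n_parsed == 0:
        raise FormatError("no gene sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc or ".", *genes]) + "\n")
    return path


def write_table(rows, path, format: str = "tsv") -> Path:
    """Write a homogeneous list of row dicts (or a DataFrame) to TSV/JSON.

    Column order is the key order of the first row; floats are serialized
    with 12 significant digits.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict(orient="records")
    rows = list(rows)
    if rows:
        schema = list(rows[0].keys())
        for r in rows[1:]:
            if list(r.keys()) != schema:
                raise ValueError("rows have mismatched schemas")
    else:
        schema = []

    def fmt(v, as_str=True):
        if isinstance(v, (float, np.floating)):
            s = format_float(float(v))
            return s if as_str else float(s)
        if isinstance(v, np.integer):
            return int(v)
        return v

    if format == "json":
        payload = [{k: fmt(v, as_str=False) for k, v in r.items()} for r in rows]
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(schema) + "\n")
            for r in rows:
                fh.write("\t".join(str(fmt(r[k])) for k in schema) + "\n")
    return path


def format_float(v: float) -> str:
    return f"{v:.12g}"


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
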