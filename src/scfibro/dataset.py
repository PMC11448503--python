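"""Core in-memory containers for the pipeline.

The central object is :class:`ExpressionDataset`, a genes × cells UMI count
matrix with aligned gene/cell identifiers and per-cell metadata.  Genes are
always rows, matching the convention of 10x-style MatrixMarket bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

META_COLUMNS = ("cluster_label", "condition", "sample_id", "dataset_id")
UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """Raised when a dataset or collection violates its invariants."""


def _as_csr(matrix) -> sp.csr_matrix:
    if sp.issparse(matrix):
        return matrix.tocsr()
    return sp.csr_matrix(np.asarray(matrix))


@dataclass
class ExpressionDataset:
    """Genes × cells count matrix with identifiers and per-cell metadata.

    Parameters
    ----------
    counts
        Sparse or dense matrix of non-negative integer UMI counts,
        shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique identifiers for rows and columns, in matrix order.
    cell_meta
        DataFrame indexed by ``cell_id`` with columns ``cluster_label``,
        ``condition``, ``sample_id`` and ``dataset_id``.  Missing columns
        are filled with the sentinel ``"unassigned"``.
    normalized
        Optional matrix of the same shape holding library-size-normalized
        log expression (see :func:`scfibro.preprocess.normalize_log`).
    embedding
        Optional ``(n_cells, d)`` array of low-dimensional coordinates.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame | None = None
    normalized: sp.csr_matrix | None = None
    embedding: np.ndarray | None = None

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta.index = self.cell_meta.index.astype(str)
        self.cell_meta.index.name = "cell_id"
        for col in META_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = UNASSIGNED
        if self.normalized is not None:
            self.normalized = _as_csr(self.normalized)
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"counts has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"counts has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if self.counts.nnz:
            data = self.counts.data
            if np.any(data < 0):
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer counts")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise ValidationError(f"cells missing from metadata: {sorted(missing)[:5]}")
        if self.cell_meta.index.duplicated().any():
            raise ValidationError("duplicate cell ids in metadata")
        # align metadata row order to cell order
        self.cell_meta = self.cell_meta.loc[self.cell_ids]
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValidationError(
                f"normalized shape {self.normalized.shape} != counts shape {self.counts.shape}"
            )
        if self.embedding is not None and self.embedding.shape[0] != n_cells:
            raise ValidationError("embedding row count != number of cells")

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def counts_row(self, gene: str) -> np.ndarray:
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()

    def normalized_row(self, gene: str) -> np.ndarray:
        if self.normalized is None:
            raise ValidationError("normalized layer not present")
        return np.asarray(self.normalized[self.gene_index(gene)].todense()).ravel()

    def cell_indices(self, cell_ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"cell {exc.args[0]!r} not present") from None

    def subset_cells(self, mask_or_ids) -> "ExpressionDataset":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = np.asarray(mask_or_ids)
            if idx.dtype.kind not in "iu":
                idx = self.cell_indices(mask_or_ids)
        cell_ids = [self.cell_ids[i] for i in idx]
        return replace(
            self,
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=cell_ids,
            cell_meta=self.cell_meta.iloc[idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
            embedding=None if self.embedding is None else self.embedding[idx],
        )

    def subset_genes(self, genes) -> "ExpressionDataset":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([lookup[g] for g in genes], dtype=int)
        return replace(
            self,
            counts=self.counts[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            cell_meta=self.cell_meta,
            normalized=None if self.normalized is None else self.normalized[idx],
            embedding=self.embedding,
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and (self.counts != other.counts).nnz == 0
            and self.cell_meta[list(META_COLUMNS)].equals(
                other.cell_meta[list(META_COLUMNS)]
            )
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics: name → (description, genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sets:
            raise ValidationError("no gene sets")
        for name, (_, genes) in self.sets.items():
            if not name:
                raise ValidationError("empty set name")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes in set {name!r}")

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets
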