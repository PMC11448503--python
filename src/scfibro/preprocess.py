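"""QC filtering, library-size normalization, HVG selection and PCA.

QC applies the gene filter (expressed in ≥ ``min_cells_per_gene`` cells)
first, then four per-cell criteria: detected genes, total UMI,
log10GenesPerUMI = log10(genes detected)/log10(total UMI), and the
mitochondrial fraction (genes matched by case-insensitive prefix).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .dataset import ExpressionDataset, ValidationError


@dataclass(frozen=True)
class QCThresholds:
    min_genes_per_cell: int = 200
    min_umi_per_cell: int = 500
    min_log10_genes_per_umi: float = 0.8
    max_mito_fraction: float = 0.30
    min_cells_per_gene: int = 3
    mito_prefix: str = "mt-"

    def __post_init__(self):
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if min(self.min_genes_per_cell, self.min_umi_per_cell,
               self.min_cells_per_gene) < 0 or self.min_log10_genes_per_umi < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QCReport:
    n_genes_in: int
    n_cells_in: int
    n_genes_removed: int
    removed_by_criterion: dict[str, int]  # per-cell criteria (non-exclusive counts)
    n_cells_removed: int
    n_genes_out: int
    n_cells_out: int


def qc_filter(dataset: ExpressionDataset, thresholds: QCThresholds | None = None):
    """Apply gene then cell QC filters; returns the filtered dataset and a report."""
    th = thresholds or QCThresholds()
    counts = dataset.counts
    cells_per_gene = np.asarray((counts > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= th.min_cells_per_gene
    genes = [g for g, k in zip(dataset.gene_ids, gene_keep) if k]
    ds = dataset.subset_genes(genes)

    c = ds.counts
    genes_detected = np.asarray((c > 0).sum(axis=0)).ravel()
    total_umi = np.asarray(c.sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(
            (genes_detected > 0) & (total_umi > 1),
            np.log10(np.maximum(genes_detected, 1)) / np.log10(np.maximum(total_umi, 2)),
            0.0,
        )
    mito_mask = np.array(
        [g.lower().startswith(th.mito_prefix.lower()) for g in ds.gene_ids]
    )
    mito_umi = (
        np.asarray(c[mito_mask].sum(axis=0)).ravel() if mito_mask.any()
        else np.zeros(ds.n_cells)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(total_umi > 0, mito_umi / np.maximum(total_umi, 1), 0.0)

    fail_genes = genes_detected < th.min_genes_per_cell
    fail_umi = total_umi < th.min_umi_per_cell
    fail_ratio = lg <= th.min_log10_genes_per_umi
    fail_mito = mito_frac >= th.max_mito_fraction
    cell_keep = ~(fail_genes | fail_umi | fail_ratio | fail_mito)
    if not cell_keep.any():
        raise ValidationError("empty after QC: no cell passes all filters")
    out = ds.subset_cells(cell_keep)
    report = QCReport(
        n_genes_in=dataset.n_genes,
        n_cells_in=dataset.n_cells,
        n_genes_removed=int((~gene_keep).sum()),
        removed_by_criterion={
            "min_genes_per_cell": int(fail_genes.sum()),
            "min_umi_per_cell": int(fail_umi.sum()),
            "min_log10_genes_per_umi": int(fail_ratio.sum()),
            "max_mito_fraction": int(fail_mito.sum()),
        },
        n_cells_removed=int((~cell_keep).sum()),
        n_genes_out=out.n_genes,
        n_cells_out=out.n_cells,
    )
    return out, report


def normalize_log(dataset: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Fill the normalized layer: ln(1 + scale·count/total_umi) per cell."""
    total = np.asarray(dataset.counts.sum(axis=0)).ravel()
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise ValidationError(f"cell {dataset.cell_ids[zero[0]]!r} has zero total UMI")
    norm = dataset.counts.tocsc(copy=True).astype(float)
    norm.data *= scale / np.repeat(total, np.diff(norm.indptr))
    norm.data = np.log1p(norm.data)
    return replace(dataset, normalized=norm.tocsr())


def select_hvgs(dataset: ExpressionDataset, n_hvgs: int, n_bins: int = 20) -> list[str]:
    """Rank genes by within-mean-bin z-scored dispersion of normalized values.

    Dispersion is variance/mean of the normalized layer; genes are binned
    into ``n_bins`` equal-count bins by mean, the dispersion is z-scored
    within each bin, and the top ``n_hvgs`` are returned (ties broken by
    gene id).
    """
    if dataset.normalized is None:
        raise ValidationError("normalized layer required")
    if n_hvgs > dataset.n_genes:
        raise ValueError(f"n_hvgs={n_hvgs} exceeds gene count {dataset.n_genes}")
    x = dataset.normalized
    n = dataset.n_cells
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / sd if sd > 0 else 0.0
    ranked = sorted(
        range(dataset.n_genes), key=lambda i: (-z[i], dataset.gene_ids[i])
    )
    return [dataset.gene_ids[i] for i in ranked[:n_hvgs]]


def pca_embed(dataset: ExpressionDataset, genes: list[str], n_components: int = 8):
    """Centered PCA of cells × selected normalized genes.

    Returns ``(embedding, loadings, explained_variance)`` with a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if dataset.normalized is None:
        raise ValidationError("normalized layer required")
    missing = set(genes) - set(dataset.gene_ids)
    if missing:
        raise KeyError(f"genes not in dataset: {sorted(missing)[:5]}")
    if n_components > min(dataset.n_cells, len(genes)):
        raise ValueError("n_components exceeds min(n_cells, n_genes)")
    sub = dataset.subset_genes(genes)
    x = np.asarray(sub.normalized.todense(), dtype=float).T  # cells × genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic signs
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    embedding = u * s
    explained = s**2 / max(x.shape[0] - 1, 1)
    return embedding, vt.T, explained
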