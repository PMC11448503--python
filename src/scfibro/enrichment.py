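"""Expressing-cell enrichment and expression-level tests per cluster.

"Expressing" means raw UMI count above a threshold (default 0, i.e. any
nonzero count).  Enrichment of expressing cells in a target cluster uses
the one-tailed hypergeometric test; expression-level differences use the
two-tailed Mann–Whitney test on the normalized layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset import ExpressionDataset, ValidationError
from .stats import TestResult, hypergeom_upper, mann_whitney


@dataclass
class ExpressingCellStats:
    gene: str
    threshold: float
    per_cluster: pd.DataFrame  # index cluster: n_cells, n_expressing, fraction


def expressing_cell_stats(dataset: ExpressionDataset, gene: str, threshold: float = 0) -> ExpressingCellStats:
    counts = dataset.counts_row(gene)
    expressing = counts > threshold
    labels = dataset.cell_meta["cluster_label"].to_numpy()
    rows = {}
    for cl in sorted(pd.unique(labels)):
        mask = labels == cl
        n, k = int(mask.sum()), int(expressing[mask].sum())
        rows[cl] = {"n_cells": n, "n_expressing": k, "fraction": k / n}
    return ExpressingCellStats(
        gene=gene,
        threshold=threshold,
        per_cluster=pd.DataFrame.from_dict(rows, orient="index"),
    )


def expressing_cell_enrichment(
    dataset: ExpressionDataset, gene: str, target_cluster: str, threshold: float = 0
) -> tuple[ExpressingCellStats, TestResult]:
    """One-tailed hypergeometric enrichment of expressing cells in a cluster.

    N = all cells, K = expressing cells overall, n = cells in the target
    cluster, k = expressing cells in the target cluster.
    """
    stats = expressing_cell_stats(dataset, gene, threshold)
    if target_cluster not in stats.per_cluster.index:
        raise ValidationError(f"cluster {target_cluster!r} not present")
    N = int(stats.per_cluster["n_cells"].sum())
    K = int(stats.per_cluster["n_expressing"].sum())
    n = int(stats.per_cluster.loc[target_cluster, "n_cells"])
    k = int(stats.per_cluster.loc[target_cluster, "n_expressing"])
    return stats, hypergeom_upper(k, K, n, N)


def expression_group_test(dataset: ExpressionDataset, gene: str, target_cluster: str) -> TestResult:
    """Two-tailed Mann–Whitney of normalized expression: cluster vs rest."""
    expr = dataset.normalized_row(gene)
    labels = dataset.cell_meta["cluster_label"].to_numpy()
    mask = labels == target_cluster
    if not mask.any() or mask.all():
        raise ValidationError("both groups must be nonempty")
    return mann_whitney(expr[mask], expr[~mask], alternative="two-sided")
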