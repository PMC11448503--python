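"""Marker derivation, Jaccard cluster similarity and reference label transfer.

Markers follow the rule: per-cluster Wilcoxon rank-sum DE versus all other
cells, keep upregulated significant genes above the cluster's 85th-percentile
log2FC cutoff with a within-cluster detection fraction of at least 40%.
Cluster similarity is the Jaccard index of marker sets.  Label transfer is a
kNN classifier in the reference's PCA space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

from .dataset import ExpressionDataset, ValidationError
from .preprocess import select_hvgs
from .stats import bh_fdr

log = logging.getLogger(__name__)


def rank_sum_markers(dataset: ExpressionDataset, min_detect_frac: float = 0.10) -> pd.DataFrame:
    """Per-cluster Mann–Whitney DE of each gene, cluster vs all other cells.

    Returns a table with columns cluster, gene, log2fc, p, q, pct_in,
    pct_out.  log2fc compares linear-scale means of expm1(normalized)
    with a pseudocount of 1; only genes detected in ≥ ``min_detect_frac``
    of either group are tested; BH adjustment is within cluster.
    """
    if dataset.normalized is None:
        raise ValidationError("normalized layer required")
    labels = dataset.cell_meta["cluster_label"].to_numpy()
    clusters = sorted(pd.unique(labels))
    for cl in clusters:
        if (labels == cl).sum() < 3:
            raise ValidationError(f"cluster {cl!r} has fewer than 3 cells")
    norm = np.asarray(dataset.normalized.todense(), dtype=float)
    lin = np.expm1(norm)
    detected = norm > 0
    rows = []
    for cl in clusters:
        in_mask = labels == cl
        out_mask = ~in_mask
        pct_in = detected[:, in_mask].mean(axis=1)
        pct_out = detected[:, out_mask].mean(axis=1)
        test = (pct_in >= min_detect_frac) | (pct_out >= min_detect_frac)
        idx = np.flatnonzero(test)
        if idx.size == 0:
            continue
        x = norm[np.ix_(idx, in_mask)]
        y = norm[np.ix_(idx, out_mask)]
        res = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=1)
        mean_in = lin[np.ix_(idx, in_mask)].mean(axis=1)
        mean_out = lin[np.ix_(idx, out_mask)].mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        q = bh_fdr(res.pvalue)
        for j, gi in enumerate(idx):
            rows.append(
                {
                    "cluster": cl,
                    "gene": dataset.gene_ids[gi],
                    "log2fc": float(log2fc[j]),
                    "p": float(res.pvalue[j]),
                    "q": float(q[j]),
                    "pct_in": float(pct_in[gi]),
                    "pct_out": float(pct_out[gi]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MarkerSets:
    sets: dict[str, list[str]]
    fc_quantile: float = 0.85
    min_prop: float = 0.40

    def __getitem__(self, cluster: str) -> list[str]:
        return self.sets[cluster]


def select_markers(
    marker_table: pd.DataFrame,
    fc_quantile: float = 0.85,
    min_prop: float = 0.40,
    q_threshold: float = 0.05,
) -> MarkerSets:
    """Apply the marker rule to a DE table.

    Per cluster: restrict to significantly upregulated rows (log2fc > 0,
    q < ``q_threshold``); the cutoff is the empirical ``fc_quantile``
    quantile (linear interpolation) of those rows' log2fc; markers are rows
    strictly above the cutoff with pct_in ≥ ``min_prop``.
    """
    sets: dict[str, list[str]] = {}
    for cl, sub in marker_table.groupby("cluster", sort=True):
        up = sub[(sub["log2fc"] > 0) & (sub["q"] < q_threshold)]
        if up.empty:
            log.warning("cluster %s has no upregulated significant genes", cl)
            sets[str(cl)] = []
            continue
        cutoff = float(np.quantile(up["log2fc"].to_numpy(), fc_quantile))
        keep = up[(up["log2fc"] > cutoff) & (up["pct_in"] >= min_prop)]
        if keep.empty:
            log.warning("cluster %s retains no markers after filtering", cl)
        sets[str(cl)] = keep.sort_values(
            "log2fc", ascending=False, kind="stable"
        )["gene"].tolist()
    return MarkerSets(sets, fc_quantile=fc_quantile, min_prop=min_prop)


def jaccard_index(a, b) -> float:
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        log.warning("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(sa & sb) / len(union)


def jaccard_matrix(marker_sets_a: MarkerSets, marker_sets_b: MarkerSets | None = None) -> pd.DataFrame:
    """Pairwise Jaccard similarity of marker sets; symmetric when b is a."""
    b = marker_sets_b or marker_sets_a
    if not any(marker_sets_a.sets.values()) or not any(b.sets.values()):
        raise ValidationError("all marker sets empty on one side")
    rows = sorted(marker_sets_a.sets)
    cols = sorted(b.sets)
    mat = pd.DataFrame(
        [[jaccard_index(marker_sets_a.sets[r], b.sets[c]) for c in cols] for r in rows],
        index=rows,
        columns=cols,
    )
    return mat


@dataclass
class LabelTransferResult:
    assignments: pd.DataFrame  # index cell_id: predicted_label, score
    k_neighbors: int
    n_pcs: int
    n_hvgs: int
    params: dict = field(default_factory=dict)


def transfer_labels(
    reference: ExpressionDataset,
    query: ExpressionDataset,
    k: int = 15,
    n_pcs: int = 30,
    n_hvgs: int = 2000,
    min_shared_genes: int = 500,
) -> LabelTransferResult:
    """Transfer reference cluster labels to query cells.

    HVGs are chosen on the reference restricted to shared genes; both
    datasets are standardized by the reference per-gene mean/sd and
    projected onto the reference PCA loadings; each query cell takes the
    majority label of its ``k`` nearest reference cells (Euclidean in PC
    space), with ties broken by summed inverse distance.  The score is the
    winning vote fraction.
    """
    if reference.normalized is None or query.normalized is None:
        raise ValidationError("normalized layers required on both datasets")
    shared = [g for g in reference.gene_ids if g in set(query.gene_ids)]
    if len(shared) < min_shared_genes:
        raise ValidationError(
            f"only {len(shared)} shared genes (< {min_shared_genes})"
        )
    if k > reference.n_cells:
        raise ValueError("k exceeds number of reference cells")
    ref = reference.subset_genes(shared)
    qry = query.subset_genes(shared)
    hvgs = select_hvgs(ref, min(n_hvgs, ref.n_genes))
    n_pcs = min(n_pcs, len(hvgs), ref.n_cells)
    ref_x = np.asarray(ref.subset_genes(hvgs).normalized.todense(), dtype=float).T
    mean = ref_x.mean(axis=0, keepdims=True)
    sd = ref_x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (ref_x - mean) / sd
    _, _, vt = randomized_svd(z, n_components=n_pcs, random_state=0)
    loadings = vt.T
    ref_pc = z @ loadings
    qry_x = np.asarray(qry.subset_genes(hvgs).normalized.todense(), dtype=float).T
    qry_pc = ((qry_x - mean) / sd) @ loadings

    nn = NearestNeighbors(n_neighbors=k).fit(ref_pc)
    dist, idx = nn.kneighbors(qry_pc)
    ref_labels = reference.cell_meta["cluster_label"].to_numpy()
    preds, scores = [], []
    inv = 1.0 / np.maximum(dist, 1e-12)
    for i in range(qry_pc.shape[0]):
        labs = ref_labels[idx[i]]
        counts: dict[str, int] = {}
        weight: dict[str, float] = {}
        for lab, w in zip(labs, inv[i]):
            counts[lab] = counts.get(lab, 0) + 1
            weight[lab] = weight.get(lab, 0.0) + w
        best = max(counts, key=lambda L: (counts[L], weight[L]))
        preds.append(best)
        scores.append(counts[best] / k)
    assignments = pd.DataFrame(
        {"predicted_label": preds, "score": scores},
        index=pd.Index(qry.cell_ids, name="cell_id"),
    )
    return LabelTransferResult(assignments, k_neighbors=k, n_pcs=n_pcs, n_hvgs=len(hvgs))
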