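"""Pseudobulk aggregation, preranked GSEA and module scoring.

The GSEA implementation follows the weighted Kolmogorov–Smirnov running-sum
statistic: genes are sorted by decreasing ranking stat; set members add
|stat|^weight normalized by the set total, non-members subtract
1/(N − N_hit).  The null distribution comes from random same-size gene sets
(gene permutation); NES divides ES by the mean |null ES| of matching sign
and the permutation p-value is (1 + #{|null| ≥ |ES|, matching sign}) /
(1 + #matching-sign nulls).  The leading edge is the set members at or
before the running-sum extremum (positive ES) or at/after it (negative ES).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, GeneSetCollection, ValidationError
from .stats import TestResult, bh_fdr, mann_whitney


# ---------------------------------------------------------------------------
# pseudobulk + ranking
# ---------------------------------------------------------------------------

def pseudobulk_aggregate(dataset: ExpressionDataset, cell_subset, by: str = "sample_id") -> pd.DataFrame:
    """Sum raw counts of the selected cells per sample: samples × genes."""
    cells = list(cell_subset)
    if not cells:
        raise ValidationError("empty cell subset")
    idx = dataset.cell_indices(cells)
    groups = dataset.cell_meta.iloc[idx][by]
    out = {}
    for sample, grp in groups.groupby(groups):
        cols = idx[np.isin(dataset.cell_meta.index[idx], grp.index)]
        out[sample] = np.asarray(dataset.counts[:, cols].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=dataset.gene_ids).T


def rank_genes(pseudobulk: pd.DataFrame, group_a_samples, group_b_samples) -> pd.Series:
    """Welch t statistic of log2(CPM+1), group A vs group B, per gene.

    Positive values mean higher expression in group A.  Genes with zero
    counts in every sample are dropped.
    """
    a = list(group_a_samples)
    b = list(group_b_samples)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 samples per group")
    mat = pseudobulk.loc[a + b]
    totals = mat.sum(axis=1).to_numpy()
    cpm = np.log2(1.0 + mat.to_numpy() * 1e6 / totals[:, None])
    nonzero = mat.to_numpy().sum(axis=0) > 0
    cpm = cpm[:, nonzero]
    genes = mat.columns[nonzero]
    xa, xb = cpm[: len(a)], cpm[len(a):]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va, vb = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    se = np.sqrt(va / len(a) + vb / len(b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / np.maximum(se, 1e-300), 0.0)
    return pd.Series(t, index=genes).sort_values(ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    q: float
    size: int
    leading_edge: list[str]
    n_perm: int
    seed: int


def _es_from_positions(pos: np.ndarray, wabs: np.ndarray, W_total: None = None):
    """ES and extremum index for one set given sorted 0-based hit positions.

    ``wabs`` is |stat|^weight over the whole ranking.  Returns
    (es, extremum_position, at_hit) where ``at_hit`` is True when the
    extremum is the value just after a hit (positive deviation).
    """
    N = wabs.size
    k = pos.size
    w = wabs[pos]
    W = w.sum()
    if W <= 0:
        # all hit stats are zero: hits contribute nothing, ES is the
        # largest miss-driven negative deviation
        w = np.ones(k)
        W = float(k)
    miss_pen = 1.0 / (N - k)
    j = np.arange(1, k + 1)
    hit_cum = np.cumsum(w) / W
    up = hit_cum - (pos + 1 - j) * miss_pen
    down = (hit_cum - w / W) - (pos - (j - 1)) * miss_pen
    i_up = int(np.argmax(up))
    i_dn = int(np.argmin(down))
    if abs(up[i_up]) >= abs(down[i_dn]):
        return float(up[i_up]), int(pos[i_up]), True
    return float(down[i_dn]), int(pos[i_dn]), False


def _null_es(N: int, k: int, wabs: np.ndarray, n_perm: int, rng: np.random.Generator,
             chunk: int = 2000) -> np.ndarray:
    """Null ES values for random size-k subsets of an N-gene ranking."""
    miss_pen = 1.0 / (N - k)
    out = np.empty(n_perm)
    j = np.arange(1, k + 1)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        r = rng.random((m, N))
        pos = np.sort(np.argpartition(r, k - 1, axis=1)[:, :k], axis=1)
        w = wabs[pos]
        W = w.sum(axis=1, keepdims=True)
        zero = W[:, 0] <= 0
        if zero.any():
            w[zero] = 1.0
            W[zero] = k
        hit_cum = np.cumsum(w, axis=1) / W
        up = hit_cum - (pos + 1 - j) * miss_pen
        down = (hit_cum - w / W) - (pos - (j - 1)) * miss_pen
        up_max = up.max(axis=1)
        dn_min = down.min(axis=1)
        es = np.where(np.abs(up_max) >= np.abs(dn_min), up_max, dn_min)
        out[done : done + m] = es
        done += m
    return out


def gsea_preranked(
    stat_vector: pd.Series,
    gene_sets: GeneSetCollection,
    n_perm: int = 100_000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> list[GseaResult]:
    """Preranked GSEA over a named ranking statistic vector.

    ``stat_vector`` maps unique gene names to ranking stats; sets are
    filtered to [min_size, max_size] after intersection with the ranked
    genes.  Deterministic given ``seed``.
    """
    stats = stat_vector.sort_values(ascending=False, kind="stable")
    if stats.index.duplicated().any():
        raise ValidationError("duplicate gene names in ranking")
    genes = list(stats.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    wabs = np.abs(stats.to_numpy()) ** weight
    rng = np.random.default_rng(seed)

    selected = []
    for name in gene_sets.names():
        members = [g for g in gene_sets.genes(name) if g in gene_pos]
        if min_size <= len(members) <= max_size and len(members) < N:
            selected.append((name, members))
    if not selected:
        raise ValidationError("no gene set passes the size filter")

    null_cache: dict[int, np.ndarray] = {}
    results = []
    for name, members in selected:
        pos = np.sort(np.array([gene_pos[g] for g in members]))
        es, ext_pos, _ = _es_from_positions(pos, wabs)
        k = pos.size
        if k not in null_cache:
            null_cache[k] = _null_es(N, k, wabs, n_perm, rng)
        null = null_cache[k]
        if es >= 0:
            matching = null[null >= 0]
            n_ge = int((matching >= es).sum())
        else:
            matching = null[null < 0]
            n_ge = int((matching <= es).sum())
        p = (1 + n_ge) / (1 + matching.size)
        denom = np.abs(matching).mean() if matching.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        if es >= 0:
            le = [genes[i] for i in pos if i <= ext_pos]
        else:
            le = [genes[i] for i in pos if i >= ext_pos]
        results.append(
            GseaResult(
                name=name, es=es, nes=float(nes), p=float(p), q=np.nan,
                size=k, leading_edge=le, n_perm=n_perm, seed=seed,
            )
        )
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def gsea_results_table(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name, "size": r.size, "es": r.es, "nes": r.nes,
                "p": r.p, "q": r.q, "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ]
    )


def leading_edge_gene_set(results: list[GseaResult], set_name: str) -> GeneSetCollection:
    """Extract a named set's leading edge as a new single-set collection."""
    for r in results:
        if r.name == set_name:
            return GeneSetCollection(
                {f"{set_name}_leading_edge": (f"leading edge of {set_name}", list(r.leading_edge))}
            )
    raise ValidationError(f"set {set_name!r} absent from results")


# ---------------------------------------------------------------------------
# module scoring
# ---------------------------------------------------------------------------

@dataclass
class ModuleScoreResult:
    scores: pd.Series  # per cell
    gene_set: list[str]
    n_bins: int
    n_ctrl: int | None
    seed: int


def module_score(
    dataset: ExpressionDataset,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int | None = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Binned-control signature score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins by mean
    normalized expression; every set gene draws ``n_ctrl`` control genes
    from its bin (excluding set genes; with replacement when the bin is
    smaller; all bin genes when ``n_ctrl`` is None).  The score is the mean
    normalized expression over set genes minus the mean over the pooled
    controls.
    """
    if dataset.normalized is None:
        raise ValidationError("normalized layer required")
    present = [g for g in gene_set if g in set(dataset.gene_ids)]
    if not present:
        raise ValidationError("no set gene present in dataset")
    rng = np.random.default_rng(seed)
    norm = dataset.normalized
    mean = np.asarray(norm.mean(axis=1)).ravel()
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(dataset.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    set_idx = np.array([dataset.gene_index(g) for g in present])
    set_mask = np.zeros(dataset.n_genes, dtype=bool)
    set_mask[set_idx] = True
    ctrl_idx: list[int] = []
    for gi in set_idx:
        pool = np.flatnonzero((bin_of == bin_of[gi]) & ~set_mask)
        if pool.size == 0:
            continue
        if n_ctrl is None:
            ctrl_idx.extend(pool.tolist())
        else:
            replace = pool.size < n_ctrl
            ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=replace).tolist())
    if not ctrl_idx:
        raise ValidationError("no control genes available")
    dense_set = np.asarray(norm[set_idx].todense(), dtype=float)
    dense_ctrl = np.asarray(norm[np.array(ctrl_idx)].todense(), dtype=float)
    scores = dense_set.mean(axis=0) - dense_ctrl.mean(axis=0)
    return ModuleScoreResult(
        scores=pd.Series(scores, index=pd.Index(dataset.cell_ids, name="cell_id")),
        gene_set=present,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def score_group_test(module_scores: ModuleScoreResult | pd.Series, groups: dict[str, list[str]]) -> TestResult:
    """Two-sided Mann–Whitney on per-cell scores between two groups of cells."""
    scores = module_scores.scores if isinstance(module_scores, ModuleScoreResult) else module_scores
    if len(groups) != 2:
        raise ValidationError("exactly two groups required")
    (ga, ca), (gb, cb) = groups.items()
    x = scores.loc[list(ca)].to_numpy()
    y = scores.loc[list(cb)].to_numpy()
    return mann_whitney(x, y, alternative="two-sided")
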