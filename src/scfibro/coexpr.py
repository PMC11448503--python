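"""Trajectory-restricted anchor-gene co-expression analysis.

Given the cells assigned to a trajectory of interest, the module correlates
every expressed gene with the anchor gene (Spearman on normalized values),
keeps genes at FDR < 0.2 (BH), intersects modules discovered in independent
datasets, builds the all-pairs correlation network over the intersection,
contrasts anchor–module correlation distributions between conditions with a
two-sample KS test, and runs hypergeometric pathway over-representation
against a user-supplied gene-set collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, GeneSetCollection, ValidationError
from .stats import bh_fdr, hypergeom_upper, ks_two_sample, spearman

log = logging.getLogger(__name__)


@dataclass
class CoexpressionModule:
    anchor: str
    dataset_id: str
    table: pd.DataFrame  # retained rows: gene, rho, p, q (|rho| descending)
    candidates: list[str]  # all genes tested (the enrichment universe)
    fdr_threshold: float
    min_detect_frac: float
    cells_used: list[str]

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()


def anchor_module(
    dataset: ExpressionDataset,
    cells,
    anchor: str,
    fdr_threshold: float = 0.2,
    min_detect_frac: float = 0.05,
) -> CoexpressionModule:
    """Discover the anchor co-expression module over the selected cells.

    Candidates are the genes (excluding the anchor) detected in at least
    ``min_detect_frac`` of the selected cells; each is Spearman-correlated
    with the anchor on the normalized layer; BH is applied across
    candidates and rows with q < ``fdr_threshold`` are retained, sorted by
    |rho| descending.
    """
    if dataset.normalized is None:
        raise ValidationError("normalized layer required")
    cells = list(cells)
    if len(cells) < 30:
        raise ValidationError(f"only {len(cells)} cells selected; need >= 30")
    idx = dataset.cell_indices(cells)
    sub = dataset.normalized[:, idx]
    dense = np.asarray(sub.todense(), dtype=float)
    try:
        ai = dataset.gene_index(anchor)
    except KeyError:
        raise ValidationError(f"anchor gene {anchor!r} not present") from None
    anchor_expr = dense[ai]
    if (anchor_expr > 0).sum() < 3:
        raise ValidationError(f"anchor {anchor!r} detected in < 3 selected cells")
    detect = (dense > 0).mean(axis=1)
    cand_idx = np.flatnonzero((detect >= min_detect_frac) & (np.arange(dense.shape[0]) != ai))
    # Spearman of every candidate against the anchor, vectorized on ranks
    import scipy.stats as ss

    ranks = ss.rankdata(dense[cand_idx], axis=1)
    ar = ss.rankdata(anchor_expr)
    arc = ar - ar.mean()
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1) * (arc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rc @ arc / denom, np.nan)
    n = len(cells)
    tstat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * ss.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(rho), 1.0, np.clip(p, 0.0, 1.0))
    rho = np.where(np.isnan(rho), 0.0, rho)
    q = bh_fdr(p)
    keep = q < fdr_threshold
    table = pd.DataFrame(
        {
            "gene": [dataset.gene_ids[i] for i in cand_idx[keep]],
            "rho": rho[keep],
            "p": p[keep],
            "q": q[keep],
        }
    ).sort_values("rho", key=np.abs, ascending=False, kind="stable").reset_index(drop=True)
    dataset_id = str(dataset.cell_meta["dataset_id"].iloc[0]) if dataset.n_cells else ""
    return CoexpressionModule(
        anchor=anchor,
        dataset_id=dataset_id,
        table=table,
        candidates=[dataset.gene_ids[i] for i in cand_idx],
        fdr_threshold=fdr_threshold,
        min_detect_frac=min_detect_frac,
        cells_used=cells,
    )


def intersect_modules(module_a: CoexpressionModule, module_b: CoexpressionModule):
    """Sorted intersection of two modules' retained genes, plus sizes."""
    if module_a.anchor != module_b.anchor:
        raise ValidationError(
            f"modules have different anchors: {module_a.anchor!r} vs {module_b.anchor!r}"
        )
    inter = sorted(set(module_a.genes) & set(module_b.genes))
    sizes = {
        module_a.dataset_id or "a": len(module_a.genes),
        module_b.dataset_id or "b": len(module_b.genes),
        "intersection": len(inter),
    }
    return inter, sizes


@dataclass
class NetworkEdges:
    anchor: str
    nodes: list[str]
    edges: pd.DataFrame  # gene_i, gene_j, rho with i<j in node order

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for r in self.edges.itertuples(index=False):
            g.add_edge(r.gene_i, r.gene_j, rho=r.rho)
        return g


def build_network(
    dataset: ExpressionDataset,
    cells,
    genes,
    anchor: str | None = None,
    edge_min_abs_rho: float = 0.0,
) -> NetworkEdges:
    """All-pairs Spearman network over ``genes`` (∪ anchor) on the cells.

    Edges with |rho| below ``edge_min_abs_rho`` are dropped (default keeps
    the complete graph).
    """
    cells = list(cells)
    if len(cells) < 30:
        raise ValidationError("need >= 30 cells for network correlations")
    nodes = list(genes)
    if anchor and anchor not in nodes:
        nodes = [anchor] + nodes
    missing = [g for g in nodes if g not in set(dataset.gene_ids)]
    if missing:
        raise ValidationError(f"gene {missing[0]!r} absent from dataset")
    if dataset.normalized is None:
        raise ValidationError("normalized layer required")
    idx = dataset.cell_indices(cells)
    import scipy.stats as ss

    gi = [dataset.gene_index(g) for g in nodes]
    dense = np.asarray(dataset.normalized[np.ix_(gi, idx)].todense(), dtype=float)
    ranks = ss.rankdata(dense, axis=1)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((rc**2).sum(axis=1))
    norms[norms == 0] = np.nan
    corr = (rc @ rc.T) / np.outer(norms, norms)
    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            r = corr[i, j]
            if np.isnan(r):
                continue
            if abs(r) >= edge_min_abs_rho:
                rows.append({"gene_i": nodes[i], "gene_j": nodes[j], "rho": float(r)})
    return NetworkEdges(
        anchor=anchor or "",
        nodes=nodes,
        edges=pd.DataFrame(rows, columns=["gene_i", "gene_j", "rho"]),
    )


def condition_correlation_comparison(
    dataset: ExpressionDataset, cells_by_condition: dict[str, list[str]], anchor: str, module
):
    """Per-condition anchor–module-gene correlation vectors and their KS test.

    ``module`` may be a :class:`CoexpressionModule` or a plain gene list.
    A module gene undetected in a condition's cells is skipped for that
    condition; if more than half the module is skipped the comparison
    aborts.
    """
    genes = module.genes if isinstance(module, CoexpressionModule) else list(module)
    if len(genes) < 2:
        raise ValidationError("module must contain >= 2 genes")
    if len(cells_by_condition) != 2:
        raise ValidationError("exactly two conditions required")
    if dataset.normalized is None:
        raise ValidationError("normalized layer required")
    vectors: dict[str, np.ndarray] = {}
    for cond, cells in cells_by_condition.items():
        cells = list(cells)
        if len(cells) < 30:
            raise ValidationError(f"condition {cond!r} has {len(cells)} cells; need >= 30")
        idx = dataset.cell_indices(cells)
        anchor_expr = np.asarray(
            dataset.normalized[dataset.gene_index(anchor), idx].todense()
        ).ravel()
        rhos, skipped = [], 0
        for g in genes:
            expr = np.asarray(
                dataset.normalized[dataset.gene_index(g), idx].todense()
            ).ravel()
            if (expr > 0).sum() == 0 or np.unique(anchor_expr).size < 2:
                skipped += 1
                log.info("gene %s undetected in condition %s; skipped", g, cond)
                continue
            rhos.append(spearman(anchor_expr, expr).statistic)
        if skipped > 0.5 * len(genes):
            raise ValidationError(
                f"more than half the module undetected in condition {cond!r}"
            )
        vectors[cond] = np.asarray(rhos)
    (c1, v1), (c2, v2) = vectors.items()
    return vectors, ks_two_sample(v1, v2)


def pathway_enrichment(
    query_genes,
    collection: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    The universe is the background of tested genes; terms are restricted to
    it before testing.  Rows with BH q < ``fdr_threshold`` are retained,
    sorted by p.
    """
    query = set(query_genes)
    universe = set(universe)
    if not query:
        raise ValidationError("empty query")
    if not query <= universe:
        raise ValidationError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name in collection.names():
        term = set(collection.genes(name)) & universe
        if not term:
            continue
        K = len(term)
        k = len(term & query)
        res = hypergeom_upper(k, K, n, N)
        rows.append(
            {"term": name, "k": k, "K": K, "n": n, "N": N, "p": res.p_value}
        )
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q"])
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df = df[df["q"] < fdr_threshold].sort_values("p", kind="stable").reset_index(drop=True)
    return df
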