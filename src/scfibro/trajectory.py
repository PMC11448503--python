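"""Origin-rooted lineage inference and pseudotime.

Lineages are paths from a designated origin cluster to each leaf of the
Euclidean minimum spanning tree over cluster centroids in a low-dimensional
embedding.  Pseudotime is the arc length from the origin centroid to a
cell's orthogonal projection onto the piecewise-linear curve through the
lineage's ordered centroids.  Pseudotime–expression association uses a
cubic B-spline least-squares fit with an F-test against the intercept-only
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
from scipy.interpolate import BSpline

from .dataset import ExpressionDataset, ValidationError
from .stats import bh_fdr


@dataclass
class LineageModel:
    origin: str
    lineages: list[list[str]]
    centroids: dict[str, np.ndarray]
    # pseudotime[cell i, lineage j]; NaN where the cell is not assigned
    pseudotime: np.ndarray | None = None
    cell_ids: list[str] | None = None
    assignment: dict[str, list[int]] = field(default_factory=dict)

    def lineage_cells(self, j: int) -> np.ndarray:
        """Indices of cells assigned to lineage j (pseudotime defined)."""
        return np.flatnonzero(~np.isnan(self.pseudotime[:, j]))


def _mst_edges(names: list[str], coords: np.ndarray) -> list[tuple[str, str]]:
    """Kruskal MST with deterministic lexicographic tie-breaking."""
    n = len(names)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((names[i], names[j]))
            d = float(np.linalg.norm(coords[i] - coords[j]))
            edges.append((d, a, b))
    edges.sort()
    parent = {nm: nm for nm in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    for d, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            out.append((a, b))
    return out


def infer_lineages(embedding: np.ndarray, cluster_labels, origin: str) -> LineageModel:
    """Build the centroid MST and enumerate origin→leaf paths.

    Returns a :class:`LineageModel` with empty pseudotime.  The model is
    invariant to rigid motions of the embedding (distances only) and fully
    deterministic (MST ties broken by lexicographic cluster-name pair).
    """
    labels = np.asarray(cluster_labels)
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] != labels.shape[0]:
        raise ValidationError("embedding rows must match cells")
    names = sorted(pd.unique(labels))
    if origin not in names:
        raise ValidationError(f"origin cluster {origin!r} absent from labels")
    if len(names) < 2:
        raise ValidationError("need at least 2 clusters")
    centroids = {nm: embedding[labels == nm].mean(axis=0) for nm in names}
    coords = np.vstack([centroids[nm] for nm in names])
    edges = _mst_edges(names, coords)
    adj: dict[str, list[str]] = {nm: [] for nm in names}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    # depth-first paths from origin to each leaf
    lineages: list[list[str]] = []

    def walk(node: str, path: list[str]):
        nxt = [n for n in sorted(adj[node]) if n not in path]
        if not nxt:
            if len(path) > 1:
                lineages.append(list(path))
            return
        for n in nxt:
            walk(n, path + [n])

    walk(origin, [origin])
    return LineageModel(origin=origin, lineages=lineages, centroids=centroids)


def _project_to_polyline(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Arc length from verts[0] to each point's nearest projection."""
    seg_start = verts[:-1]
    seg_vec = verts[1:] - seg_start
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d = np.full(points.shape[0], np.inf)
    best_s = np.zeros(points.shape[0])
    for k in range(seg_start.shape[0]):
        v = seg_vec[k]
        L2 = seg_len[k] ** 2
        if L2 == 0:
            tproj = np.zeros(points.shape[0])
        else:
            tproj = np.clip((points - seg_start[k]) @ v / L2, 0.0, 1.0)
        proj = seg_start[k] + tproj[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_s[upd] = cum[k] + tproj[upd] * seg_len[k]
    return best_s


def compute_pseudotime(
    model: LineageModel, embedding: np.ndarray, cluster_labels, cell_ids=None
) -> LineageModel:
    """Fill per-cell, per-lineage pseudotime into the model.

    A cell is assigned to every lineage whose cluster path contains its
    cluster; its pseudotime on that lineage is the arc length from the
    origin centroid to its orthogonal projection on the piecewise-linear
    centroid curve.
    """
    labels = np.asarray(cluster_labels)
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if not model.lineages:
        raise ValidationError("model has no lineages")
    pt = np.full((n, len(model.lineages)), np.nan)
    for j, path in enumerate(model.lineages):
        if len(path) < 2:
            raise ValidationError(f"lineage {j} has fewer than 2 clusters")
        verts = np.vstack([model.centroids[c] for c in path])
        mask = np.isin(labels, path)
        if mask.any():
            pt[mask, j] = _project_to_polyline(embedding[mask], verts)
    model.pseudotime = pt
    model.cell_ids = list(cell_ids) if cell_ids is not None else [str(i) for i in range(n)]
    model.assignment = {}
    for i in range(n):
        lin = [j for j in range(len(model.lineages)) if not np.isnan(pt[i, j])]
        model.assignment[model.cell_ids[i]] = lin
    return model


@dataclass
class PseudotimeFit:
    gene: str
    lineage: int
    df: int
    coefficients: np.ndarray
    grid: np.ndarray
    fitted: np.ndarray
    f_statistic: float
    p_association: float
    n_cells: int


def _bspline_basis(t: np.ndarray, df: int, t_ref: np.ndarray | None = None) -> np.ndarray:
    """Cubic B-spline basis with df functions, interior knots at quantiles."""
    ref = t if t_ref is None else t_ref
    degree = 3
    n_interior = df - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(ref, qs)
    else:
        interior = np.array([])
    lo, hi = float(ref.min()), float(ref.max())
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    tt = np.clip(t, lo, hi)
    design = BSpline.design_matrix(tt, knots, degree, extrapolate=False).toarray()
    return design


def fit_pseudotime_gam(pseudotime, expression, df: int = 5, gene: str = "", lineage: int = 0) -> PseudotimeFit:
    """Least-squares cubic B-spline fit of expression on pseudotime.

    The association p-value is the F-test of the spline model against the
    intercept-only model, with Gaussian errors on the normalized expression
    scale.
    """
    t = np.asarray(pseudotime, dtype=float)
    y = np.asarray(expression, dtype=float)
    if df < 3:
        raise ValueError("df must be >= 3")
    ok = ~(np.isnan(t) | np.isnan(y))
    t, y = t[ok], y[ok]
    n = t.size
    if n < 20:
        raise ValidationError("need at least 20 cells with defined pseudotime")
    if n <= df + 1:
        raise ValidationError("fewer cells than model parameters")
    basis = _bspline_basis(t, df)
    X = np.column_stack([np.ones(n), basis])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted_vals = X @ coef
    rss1 = float(np.sum((y - fitted_vals) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    # the spline basis spans the intercept; extra parameters = rank(X) - 1
    rank = np.linalg.matrix_rank(X)
    p_extra = rank - 1
    dof2 = n - rank
    if p_extra <= 0 or dof2 <= 0:
        raise ValidationError("degenerate design")
    if rss0 <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        # constant response: the intercept-only model is already exact
        f_stat, p = 0.0, 1.0
    elif rss1 <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ((rss0 - rss1) / p_extra) / (rss1 / dof2)
        f_stat = max(f_stat, 0.0)
        p = float(ss.f.sf(f_stat, p_extra, dof2))
    grid = np.linspace(t.min(), t.max(), 100)
    grid_X = np.column_stack([np.ones(grid.size), _bspline_basis(grid, df, t_ref=t)])
    return PseudotimeFit(
        gene=gene,
        lineage=lineage,
        df=df,
        coefficients=coef,
        grid=grid,
        fitted=grid_X @ coef,
        f_statistic=float(f_stat),
        p_association=min(max(p, 0.0), 1.0),
        n_cells=n,
    )


def anchor_trajectory_report(
    dataset: ExpressionDataset, model: LineageModel, anchor_gene: str, df: int = 5, alpha: float = 0.05
):
    """Fit the anchor gene against pseudotime on every lineage.

    Returns ``(fits, summary)`` where the summary table carries per-lineage
    p, BH q, the fitted mean over the terminal pseudotime decile, and a flag
    for anchor-associated lineages (q < ``alpha``).
    """
    if model.pseudotime is None:
        raise ValidationError("pseudotime not computed")
    expr = dataset.normalized_row(anchor_gene)
    fits, rows = [], []
    for j, path in enumerate(model.lineages):
        pt = model.pseudotime[:, j]
        fit = fit_pseudotime_gam(pt, expr, df=df, gene=anchor_gene, lineage=j)
        fits.append(fit)
        ok = ~np.isnan(pt)
        hi = np.quantile(pt[ok], 0.9)
        terminal_mask = ok & (pt >= hi)
        rows.append(
            {
                "lineage": j,
                "path": "->".join(path),
                "n_cells": fit.n_cells,
                "f_statistic": fit.f_statistic,
                "p": fit.p_association,
                "terminal_decile_fitted_mean": float(
                    np.mean(fit.fitted[fit.grid >= np.quantile(fit.grid, 0.9)])
                ),
                "terminal_decile_observed_mean": float(expr[terminal_mask].mean()),
            }
        )
    summary = pd.DataFrame(rows)
    summary["q"] = bh_fdr(summary["p"].to_numpy())
    summary["anchor_associated"] = summary["q"] < alpha
    return fits, summary
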