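"""QC, normalization, HVG and PCA tests.

The QC fixture is an 8-cell matrix designed so that exactly one cell
violates each of the four per-cell criteria (the detected-genes violator
also fails the log10GenesPerUMI rule by construction) and one gene is seen
in only 2 cells.  Hand enumeration: 4 surviving cells, 9 surviving genes.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scfibro.dataset import ExpressionDataset, ValidationError
from scfibro.preprocess import QCThresholds, normalize_log, pca_embed, qc_filter, select_hvgs


def build_qc_fixture():
    """10 genes × 8 cells; thresholds: ≥5 genes, ≥10 UMI, >0.8 ratio, <30% mito,
    gene in ≥3 cells.  Columns: 4 passing cells, then one violator per rule."""
    genes = [f"G{i}" for i in range(1, 9)] + ["G9_rare", "mt-1"]
    cols = {
        # detected genes / total UMI (after the rare gene is filtered) chosen
        # to keep log10(genes)/log10(umi) above 0.8 for passing cells
        "pass1": {"G1": 2, "G2": 2, "G3": 2, "G4": 1, "G5": 1, "G6": 1, "G7": 2, "G9_rare": 1},
        "pass2": {"G1": 2, "G2": 2, "G3": 2, "G4": 2, "G5": 1, "G6": 1, "G7": 1, "G9_rare": 1},
        "pass3": {"G1": 2, "G2": 1, "G3": 1, "G4": 1, "G5": 1, "G6": 1, "G7": 1, "G8": 1, "mt-1": 1},
        "pass4": {"G1": 2, "G2": 2, "G3": 2, "G4": 2, "G5": 1, "G6": 1, "G7": 1, "G8": 1, "mt-1": 1},
        "fail_genes": {"G1": 3, "G2": 3, "G3": 2, "G4": 2},  # 4 genes (also fails ratio)
        "fail_umi": {"G1": 2, "G2": 1, "G3": 1, "G4": 1, "G5": 1, "G6": 1, "G7": 1, "G8": 1},  # 9 UMI
        "fail_ratio": {"G1": 10, "G2": 8, "G3": 5, "G4": 4, "G5": 3},  # 5 genes, 30 UMI
        "fail_mito": {"mt-1": 4, "G1": 1, "G2": 1, "G3": 1, "G4": 1, "G5": 1, "G6": 1, "G7": 1, "G8": 1},
    }
    mat = np.zeros((len(genes), len(cols)), dtype=int)
    for j, (cell, vals) in enumerate(cols.items()):
        for g, v in vals.items():
            mat[genes.index(g), j] = v
    meta = pd.DataFrame(
        {"cluster_label": "X", "condition": "Control", "sample_id": "s", "dataset_id": "d"},
        index=pd.Index(list(cols), name="cell_id"),
    )
    ds = ExpressionDataset(sp.csr_matrix(mat), genes, list(cols), meta)
    th = QCThresholds(
        min_genes_per_cell=5, min_umi_per_cell=10,
        min_log10_genes_per_umi=0.8, max_mito_fraction=0.30, min_cells_per_gene=3,
    )
    return ds, th


def test_qc_fixture_hand_enumeration():
    ds, th = build_qc_fixture()
    out, report = qc_filter(ds, th)
    assert out.cell_ids == ["pass1", "pass2", "pass3", "pass4"]
    assert "G9_rare" not in out.gene_ids and out.n_genes == 9
    assert report.n_genes_removed == 1
    assert report.removed_by_criterion == {
        "min_genes_per_cell": 1,
        "min_umi_per_cell": 1,
        "min_log10_genes_per_umi": 2,  # fail_genes violates this one too
        "max_mito_fraction": 1,
    }


def test_qc_ratio_formula_example():
    # 100 detected genes, 1000 UMI -> log10GenesPerUMI = 2/3 < 0.8 -> removed
    n_genes = 120
    counts = np.zeros((n_genes, 2), dtype=int)
    counts[:100, 0] = 10  # cell 0: 100 genes, 1000 UMI
    counts[:110, 1] = 1
    counts[0, 1] = 3      # cell 1: 110 genes, 112 UMI, ratio 0.996
    ds = ExpressionDataset(
        sp.csr_matrix(counts), [f"g{i}" for i in range(n_genes)], ["c0", "c1"],
    )
    th = QCThresholds(min_genes_per_cell=1, min_umi_per_cell=1, min_cells_per_gene=0)
    out, _ = qc_filter(ds, th)
    assert out.cell_ids == ["c1"]


def test_qc_mito_fraction_threshold():
    counts = np.array([[4, 1], [6, 9]])  # gene 0 is mito: 40% vs 10%
    ds = ExpressionDataset(sp.csr_matrix(counts), ["mt-x", "g1"], ["c0", "c1"])
    th = QCThresholds(min_genes_per_cell=0, min_umi_per_cell=0,
                      min_log10_genes_per_umi=0.0, min_cells_per_gene=0)
    out, _ = qc_filter(ds, th)
    assert out.cell_ids == ["c1"]


def test_qc_idempotent(sim_factory):
    ds, _ = sim_factory(0)
    once, _ = qc_filter(ds)
    twice, rep = qc_filter(once)
    assert twice.cell_ids == once.cell_ids
    assert twice.gene_ids == once.gene_ids
    assert rep.n_cells_removed == 0


def test_qc_all_cells_removed_errors():
    ds = ExpressionDataset(sp.csr_matrix(np.ones((3, 2), dtype=int)), ["a", "b", "c"], ["x", "y"])
    with pytest.raises(ValidationError, match="empty after QC"):
        qc_filter(ds, QCThresholds(min_umi_per_cell=100, min_cells_per_gene=0))


# -- normalization ----------------------------------------------------------

def test_normalize_formula():
    counts = np.array([[2], [2]])
    ds = ExpressionDataset(sp.csr_matrix(counts), ["a", "b"], ["c0"])
    norm = normalize_log(ds, scale=10)
    vals = np.asarray(norm.normalized.todense()).ravel()
    np.testing.assert_allclose(vals, np.log(1 + 5.0), rtol=1e-12)


def test_normalize_preserves_zeros_and_is_monotone():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 6, (20, 10))
    counts[:, 0] += 1  # ensure no zero-UMI cell
    counts[3] = 0  # all-zero gene
    ds = ExpressionDataset(
        sp.csr_matrix(counts), [f"g{i}" for i in range(20)], [f"c{i}" for i in range(10)]
    )
    n1 = np.asarray(normalize_log(ds, scale=1e4).normalized.todense())
    n2 = np.asarray(normalize_log(ds, scale=2e4).normalized.todense())
    assert (n1[3] == 0).all()
    assert ((n1 == 0) == (counts == 0)).all()
    nz = counts > 0
    assert (n2[nz] > n1[nz]).all()
    # within a cell, larger counts get larger normalized values
    col = n1[:, 1]
    c = counts[:, 1]
    order = np.argsort(c)
    assert (np.diff(col[order]) >= 0).all()


def test_normalize_zero_total_cell_errors():
    counts = np.array([[1, 0], [1, 0]])
    ds = ExpressionDataset(sp.csr_matrix(counts), ["a", "b"], ["good", "empty"])
    with pytest.raises(ValidationError, match="empty"):
        normalize_log(ds)


# -- HVGs -------------------------------------------------------------------

def test_hvgs_deterministic_and_constant_genes_rank_last(sim_factory):
    ds, _ = sim_factory(0)
    top1 = select_hvgs(ds, 500)
    top2 = select_hvgs(ds, 500)
    assert top1 == top2
    # all-zero genes (zero variance) never appear in a top list shorter than
    # the number of varying genes
    zero_rows = np.asarray((ds.normalized > 0).sum(axis=1)).ravel() == 0
    zeros = {g for g, z in zip(ds.gene_ids, zero_rows) if z}
    assert not (set(top1) & zeros)


def test_hvgs_recover_planted_signal_genes(sim_factory):
    fracs = []
    for seed in range(3):
        ds, truth = sim_factory(seed)
        planted = set(truth.genes.index[
            truth.genes["is_anchor"] | truth.genes["is_module"] | (truth.genes["is_de_for"] != "")
        ]) & set(ds.gene_ids)
        top = set(select_hvgs(ds, 500))
        fracs.append(len(top & planted) / len(planted))
    assert np.mean(fracs) >= 0.6


def test_hvgs_too_many_requested_errors(toy_dataset):
    ds = normalize_log(toy_dataset)
    with pytest.raises(ValueError):
        select_hvgs(ds, 10)


# -- PCA --------------------------------------------------------------------

def test_pca_rank_one_structure():
    rng = np.random.default_rng(1)
    u = rng.normal(size=30)
    v = np.abs(rng.normal(size=10)) + 0.5
    x = np.outer(v, u) + rng.normal(0, 1e-4, (10, 30))
    x -= x.min()
    counts = np.round(x * 10).astype(int)
    ds = ExpressionDataset(
        sp.csr_matrix(counts), [f"g{i}" for i in range(10)], [f"c{i}" for i in range(30)]
    )
    ds.normalized = sp.csr_matrix(x)
    emb, load, ev = pca_embed(ds, ds.gene_ids, n_components=3)
    assert ev[0] / ev.sum() > 0.99
    assert (np.diff(ev) <= 1e-12).all()


def test_pca_sign_convention_reproducible(sim_factory):
    ds, _ = sim_factory(0)
    genes = select_hvgs(ds, 100)
    e1, l1, _ = pca_embed(ds, genes, 4)
    e2, l2, _ = pca_embed(ds, genes, 4)
    np.testing.assert_array_equal(e1, e2)
    for j in range(4):
        assert l1[np.argmax(np.abs(l1[:, j])), j] > 0


def test_pca_component_limit_errors(toy_dataset):
    ds = normalize_log(toy_dataset)
    with pytest.raises(ValueError):
        pca_embed(ds, ds.gene_ids, n_components=5)
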