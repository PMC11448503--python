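"""Shared fixtures: cached prepared simulations and small toy datasets."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest
import scipy.sparse as sp

from scfibro.dataset import ExpressionDataset
from scfibro.preprocess import normalize_log, qc_filter
from scfibro.synthetic import SimConfig, generate_dataset, generate_paired_datasets


@lru_cache(maxsize=10)
def prepared_sim(seed: int):
    """QC-filtered, normalized default simulation plus truth (cached)."""
    ds, truth = generate_dataset(SimConfig(seed=seed))
    ds, _ = qc_filter(ds)
    ds = normalize_log(ds)
    ds.normalized = ds.normalized.astype(np.float32)
    return ds, truth


@lru_cache(maxsize=2)
def prepared_pair(seed: int):
    """QC-filtered, normalized ref/query pair plus truths (cached)."""
    (ref, t_ref), (qry, t_qry) = generate_paired_datasets(SimConfig(seed=seed))
    ref, _ = qc_filter(ref)
    qry, _ = qc_filter(qry)
    ref, qry = normalize_log(ref), normalize_log(qry)
    ref.normalized = ref.normalized.astype(np.float32)
    qry.normalized = qry.normalized.astype(np.float32)
    return ref, t_ref, qry, t_qry


@pytest.fixture(scope="session")
def sim_factory():
    return prepared_sim


@pytest.fixture(scope="session")
def pair_factory():
    return prepared_pair


@pytest.fixture()
def toy_dataset():
    """3 genes × 4 cells with explicit counts and cluster labels."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 4],
            [1, 1, 1, 1],
        ]
    )
    import pandas as pd

    meta = pd.DataFrame(
        {
            "cluster_label": ["A", "A", "B", "B"],
            "condition": ["Control", "PF", "Control", "PF"],
            "sample_id": ["s1", "s1", "s2", "s2"],
            "dataset_id": ["toy"] * 4,
        },
        index=pd.Index([f"c{i}" for i in range(4)], name="cell_id"),
    )
    return ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=["g1", "g2", "g3"],
        cell_ids=[f"c{i}" for i in range(4)],
        cell_meta=meta,
    )
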