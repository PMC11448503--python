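"""End-to-end orchestration of the analysis graph.

``run_pipeline`` executes, on a reference dataset (plus an optional query
dataset for label transfer):  QC → normalization → label transfer →
markers + Jaccard similarity → origin-rooted lineages + pseudotime →
anchor–pseudotime association → anchor co-expression module per dataset →
cross-dataset intersection → correlation network → condition KS contrast →
pathway enrichment → expressing-cell enrichment, and (when gene sets and
two sample groups are available) pseudobulk ranking → preranked GSEA →
leading-edge set → module scores.  Every stage writes its artifact under
``out_dir`` and is recorded in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import coexpr, enrichment, io_formats, markers, preprocess, signatures, trajectory
from .dataset import ExpressionDataset, ValidationError
from .preprocess import QCThresholds

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    ref_bundle: str | None = None
    query_bundle: str | None = None
    origin_cluster: str = "transitional_AT2"
    aberrant_cluster: str = "aberrant_basaloid"
    anchor_gene: str = "IL11"
    disease_condition: str = "PF"
    control_condition: str = "Control"
    qc: QCThresholds = field(default_factory=QCThresholds)
    fdr_module: float = 0.2
    fdr_pathway: float = 0.1
    fc_quantile: float = 0.85
    min_prop: float = 0.40
    min_detect_frac: float = 0.05
    gsea_n_perm: int = 100_000
    gsea_weight: float = 1.0
    gmt_path: str | None = None
    n_hvgs: int = 2000
    n_pcs: int = 30
    k_neighbors: int = 15
    seed: int = 0
    out_dir: str = "scfibro_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QCThresholds(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_bundle(bundle_dir: str) -> ExpressionDataset:
    d = Path(bundle_dir)
    meta = d / "cell_meta.tsv"
    return io_formats.read_mtx_bundle(
        d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv",
        meta if meta.exists() else None,
    )


def _stage(manifest: dict, name: str, fn):
    t0 = time.time()
    try:
        out = fn()
    except Exception:
        manifest["stages"].append({"stage": name, "status": "failed"})
        raise
    manifest["stages"].append(
        {"stage": name, "status": "ok", "seconds": round(time.time() - t0, 3)}
    )
    return out


def aberrant_lineage_index(model: trajectory.LineageModel, aberrant_cluster: str) -> int:
    for j, path in enumerate(model.lineages):
        if path[-1] == aberrant_cluster:
            return j
    raise ValidationError(
        f"no lineage terminates at aberrant cluster {aberrant_cluster!r}"
    )


def _analyse_dataset(ds: ExpressionDataset, cfg: PipelineConfig, out: Path, tag: str, manifest: dict):
    """QC/normalize/trajectory/module for one dataset; returns artifacts."""
    ds_qc, report = _stage(manifest, f"qc[{tag}]", lambda: preprocess.qc_filter(ds, cfg.qc))
    (out / f"qc_report_{tag}.json").write_text(
        json.dumps(asdict(report), indent=1), encoding="utf-8"
    )
    ds_qc = preprocess.normalize_log(ds_qc)

    labels = ds_qc.cell_meta["cluster_label"].to_numpy()
    if ds_qc.embedding is None:
        hvgs = preprocess.select_hvgs(ds_qc, min(cfg.n_hvgs, ds_qc.n_genes))
        emb, _, _ = preprocess.pca_embed(ds_qc, hvgs, n_components=min(8, len(hvgs)))
        ds_qc.embedding = emb[:, :2]
    model = _stage(
        manifest,
        f"lineages[{tag}]",
        lambda: trajectory.compute_pseudotime(
            trajectory.infer_lineages(ds_qc.embedding, labels, cfg.origin_cluster),
            ds_qc.embedding, labels, ds_qc.cell_ids,
        ),
    )
    pt_rows = []
    for j in range(len(model.lineages)):
        for i in model.lineage_cells(j):
            pt_rows.append(
                {"cell_id": model.cell_ids[i], "lineage": j,
                 "pseudotime": float(model.pseudotime[i, j])}
            )
    io_formats.write_table(pt_rows, out / f"pseudotime_{tag}.tsv")
    (out / f"lineages_{tag}.json").write_text(
        json.dumps(
            {"origin": model.origin, "lineages": model.lineages,
             "centroids": {k: list(map(float, v)) for k, v in model.centroids.items()}},
            indent=1,
        ),
        encoding="utf-8",
    )

    fits, traj_summary = _stage(
        manifest,
        f"anchor_trajectory[{tag}]",
        lambda: trajectory.anchor_trajectory_report(ds_qc, model, cfg.anchor_gene),
    )
    io_formats.write_table(traj_summary, out / f"anchor_trajectory_{tag}.tsv")

    j_ab = aberrant_lineage_index(model, cfg.aberrant_cluster)
    traj_cells = [model.cell_ids[i] for i in model.lineage_cells(j_ab)]
    module = _stage(
        manifest,
        f"anchor_module[{tag}]",
        lambda: coexpr.anchor_module(
            ds_qc, traj_cells, cfg.anchor_gene,
            fdr_threshold=cfg.fdr_module, min_detect_frac=cfg.min_detect_frac,
        ),
    )
    io_formats.write_table(module.table, out / f"module_{tag}.tsv")
    return ds_qc, model, module, traj_cells


def run_pipeline(config: PipelineConfig, ref: ExpressionDataset | None = None,
                 query: ExpressionDataset | None = None) -> dict:
    """Run the full analysis graph; returns the manifest dict.

    Datasets may be passed in memory or loaded from the configured MTX
    bundles.  All randomness is seeded from ``config.seed`` via named
    substreams.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "stages": [],
        "outputs": {},
    }
    if ref is None:
        if cfg.ref_bundle is None:
            raise ValidationError("no reference dataset given")
        ref = _load_bundle(cfg.ref_bundle)
    if query is None and cfg.query_bundle:
        query = _load_bundle(cfg.query_bundle)
    if cfg.anchor_gene not in set(ref.gene_ids):
        raise ValidationError(f"anchor gene {cfg.anchor_gene!r} absent from reference")

    ref_qc, ref_model, ref_module, ref_traj_cells = _analyse_dataset(
        ref, cfg, out, "ref", manifest
    )

    # markers + Jaccard on the reference
    mtable = _stage(manifest, "markers[ref]", lambda: markers.rank_sum_markers(ref_qc))
    io_formats.write_table(mtable, out / "markers_ref.tsv")
    msets = markers.select_markers(mtable, cfg.fc_quantile, cfg.min_prop)
    jac = markers.jaccard_matrix(msets)
    jac.to_csv(out / "jaccard_ref.tsv", sep="\t")

    query_module = None
    if query is not None:
        query_qc, qc_rep = preprocess.qc_filter(query, cfg.qc)
        query_qc = preprocess.normalize_log(query_qc)
        transfer = _stage(
            manifest,
            "label_transfer",
            lambda: markers.transfer_labels(
                ref_qc, query_qc, k=cfg.k_neighbors, n_pcs=cfg.n_pcs, n_hvgs=cfg.n_hvgs
            ),
        )
        tr = transfer.assignments.reset_index()
        io_formats.write_table(tr, out / "label_transfer.tsv")
        query_qc.cell_meta["cluster_label"] = transfer.assignments["predicted_label"]
        # Jaccard QC of transfer: markers from transferred labels vs reference markers
        qtable = markers.rank_sum_markers(query_qc)
        qsets = markers.select_markers(qtable, cfg.fc_quantile, cfg.min_prop)
        jac_qc = markers.jaccard_matrix(msets, qsets)
        jac_qc.to_csv(out / "jaccard_transfer_qc.tsv", sep="\t")

        _, _, query_module, _ = _analyse_dataset(query_qc, cfg, out, "query", manifest)

    # intersection + network
    if query_module is not None:
        inter, sizes = coexpr.intersect_modules(ref_module, query_module)
        (out / "module_intersection.json").write_text(
            json.dumps({"genes": inter, "sizes": sizes}, indent=1), encoding="utf-8"
        )
        net_genes = inter if len(inter) >= 2 else ref_module.genes
    else:
        net_genes = ref_module.genes
    if len(net_genes) >= 2:
        net = _stage(
            manifest,
            "network",
            lambda: coexpr.build_network(
                ref_qc, ref_traj_cells, net_genes, anchor=cfg.anchor_gene
            ),
        )
        io_formats.write_table(
            [{"gene": g} for g in net.nodes], out / "network_nodes.tsv"
        )
        io_formats.write_table(net.edges, out / "network_edges.tsv")

    # condition contrast of anchor-module correlations on trajectory cells
    cond = ref_qc.cell_meta.loc[ref_traj_cells, "condition"]
    cells_by_cond = {
        cfg.control_condition: cond.index[cond == cfg.control_condition].tolist(),
        cfg.disease_condition: cond.index[cond == cfg.disease_condition].tolist(),
    }
    if all(len(v) >= 30 for v in cells_by_cond.values()) and len(ref_module.genes) >= 2:
        vectors, ks = _stage(
            manifest,
            "condition_ks",
            lambda: coexpr.condition_correlation_comparison(
                ref_qc, cells_by_cond, cfg.anchor_gene, ref_module
            ),
        )
        (out / "condition_ks.json").write_text(
            json.dumps(
                {
                    "D": ks.statistic, "p": ks.p_value,
                    **{c: list(map(float, v)) for c, v in vectors.items()},
                },
                indent=1,
            ),
            encoding="utf-8",
        )
        manifest["outputs"]["condition_ks_p"] = ks.p_value

    # pathway enrichment of the module against a user GMT
    if cfg.gmt_path:
        collection = io_formats.read_gmt(cfg.gmt_path)
        enr = _stage(
            manifest,
            "pathway_enrichment",
            lambda: coexpr.pathway_enrichment(
                [g for g in ref_module.genes if g in set(ref_module.candidates)],
                collection, ref_module.candidates, fdr_threshold=cfg.fdr_pathway,
            ),
        )
        io_formats.write_table(enr, out / "pathway_enrichment.tsv")

    # expressing-cell enrichment + expression test for the anchor
    stats, hyp = _stage(
        manifest,
        "expressing_enrichment",
        lambda: enrichment.expressing_cell_enrichment(
            ref_qc, cfg.anchor_gene, cfg.aberrant_cluster
        ),
    )
    mw = enrichment.expression_group_test(ref_qc, cfg.anchor_gene, cfg.aberrant_cluster)
    tbl = stats.per_cluster.reset_index(names="cluster")
    io_formats.write_table(tbl, out / "expressing_cells.tsv")
    manifest["outputs"]["expressing_enrichment_p"] = hyp.p_value
    manifest["outputs"]["expression_mw_p"] = mw.p_value

    # optional signature stage: pseudobulk GSEA on the aberrant cluster
    ab_cells = ref_qc.cell_meta.index[
        ref_qc.cell_meta["cluster_label"] == cfg.aberrant_cluster
    ].tolist()
    samples = ref_qc.cell_meta.loc[ab_cells]
    ga = sorted(samples.loc[samples["condition"] == cfg.disease_condition, "sample_id"].unique())
    gb = sorted(samples.loc[samples["condition"] == cfg.control_condition, "sample_id"].unique())
    if cfg.gmt_path and len(ga) >= 2 and len(gb) >= 2:
        pb = signatures.pseudobulk_aggregate(ref_qc, ab_cells)
        ranks = signatures.rank_genes(pb, ga, gb)
        io_formats.write_table(
            [{"gene": g, "stat": float(s)} for g, s in ranks.items()],
            out / "ranking.tsv",
        )
        collection = io_formats.read_gmt(cfg.gmt_path)
        try:
            gsea = _stage(
                manifest,
                "gsea",
                lambda: signatures.gsea_preranked(
                    ranks, collection, n_perm=cfg.gsea_n_perm,
                    weight=cfg.gsea_weight, seed=cfg.seed,
                ),
            )
        except ValidationError:
            gsea = []
        if gsea:
            io_formats.write_table(signatures.gsea_results_table(gsea), out / "gsea.tsv")
            top = min(gsea, key=lambda r: r.p)
            le = signatures.leading_edge_gene_set(gsea, top.name)
            io_formats.write_gmt(le, out / "leading_edge.gmt")
            score = signatures.module_score(
                ref_qc, le.genes(f"{top.name}_leading_edge"), seed=cfg.seed
            )
            io_formats.write_table(
                score.scores.rename("score").reset_index(), out / "module_scores.tsv"
            )
            cond_all = ref_qc.cell_meta["condition"]
            grp = {
                cfg.disease_condition: cond_all.index[cond_all == cfg.disease_condition].tolist(),
                cfg.control_condition: cond_all.index[cond_all == cfg.control_condition].tolist(),
            }
            if all(grp.values()):
                res = signatures.score_group_test(score, grp)
                manifest["outputs"]["module_score_mw_p"] = res.p_value

    manifest["outputs"]["n_lineages_ref"] = len(ref_model.lineages)
    manifest["outputs"]["module_size_ref"] = len(ref_module.genes)
    if query_module is not None:
        manifest["outputs"]["module_size_query"] = len(query_module.genes)
        manifest["outputs"]["module_size_intersection"] = len(inter)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
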