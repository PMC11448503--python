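# scfibro

Trajectory-restricted anchor-gene co-expression analysis for single-cell
RNA-seq of fibrotic lung epithelium.

## The problem

In human pulmonary fibrosis, alveolar repair derails: transitional AT2
cells, instead of completing differentiation into AT1 cells, can divert
into a disease-specific aberrant epithelial state (KRT5−/KRT17+ /
"aberrant basaloid" cells; Krt8+ ADI in mouse). A cytokine of interest —
the *anchor gene*, e.g. *IL11* — may mark and drive this aberrant path.
`scfibro` implements the computational workflow that characterizes such an
anchor along the bifurcating differentiation trajectory:

- **QC and normalization** with the standard per-cell filters
  (≥200 genes, ≥500 UMI, log10GenesPerUMI > 0.8, mitochondrial
  fraction < 30%, genes in ≥3 cells) and log library-size normalization.
- **Marker-based cluster similarity**: per-cluster Wilcoxon rank-sum DE,
  markers = upregulated genes above the cluster's 85th-percentile log2FC
  with ≥40% within-cluster detection, compared across clusters by the
  Jaccard index J(A,B) = |A∩B| / |A∪B|.
- **Reference label transfer**: a kNN classifier in the reference's PCA
  space, quality-controlled by the Jaccard similarity of transferred-label
  markers versus native markers.
- **Origin-rooted trajectory inference**: minimum spanning tree over
  cluster centroids; lineages are the tree paths from the designated origin
  cluster to each leaf; pseudotime is arc length along the piecewise-linear
  centroid curve. Anchor–pseudotime association is a cubic B-spline
  regression with an F-test (a GAM on normalized expression).
- **Anchor co-expression module**: Spearman correlation of every expressed
  gene with the anchor over trajectory-assigned cells, Benjamini–Hochberg
  FDR < 0.2; modules from independent datasets are intersected; the
  module's all-pairs correlation network is exported as node/edge tables.
- **Condition contrast**: the distribution of anchor–module correlations
  in control versus disease cells, compared with a two-sample
  Kolmogorov–Smirnov test.
- **Enrichment statistics**: one-tailed hypergeometric tests for
  expressing-cell enrichment per cluster, Mann–Whitney expression tests,
  and hypergeometric pathway over-representation (FDR < 0.1) against GMT
  gene-set collections.
- **Signatures**: pseudobulk aggregation, a Welch-t ranking statistic,
  preranked permutation GSEA (weighted running-sum ES, gene-permutation
  null, sign-matched NES, 10⁵ permutations by default), leading-edge
  gene-set construction, and binned-control module scoring with a
  Wilcoxon group test.

A seeded synthetic-data generator (`scfibro.synthetic`) produces
negative-binomial count matrices with the full structure these analyses
assume — a bifurcating latent trajectory, an anchor gene rising along one
branch, a 40-gene module coupled to the anchor through a latent factor
only in the disease condition, cluster-specific DE genes, and batch-paired
dataset pairs — together with complete ground truth, so every stage is
benchmarked against known truth.

## Worked example

```python
from scfibro.synthetic import SimConfig, generate_dataset
from scfibro.preprocess import qc_filter, normalize_log
from scfibro.trajectory import infer_lineages, compute_pseudotime, anchor_trajectory_report
from scfibro.coexpr import anchor_module

ds, truth = generate_dataset(SimConfig(seed=0))
ds, report = qc_filter(ds)
ds = normalize_log(ds)
labels = ds.cell_meta["cluster_label"].to_numpy()
model = compute_pseudotime(
    infer_lineages(ds.embedding, labels, "transitional_AT2"),
    ds.embedding, labels, ds.cell_ids,
)
print([">".join(p) for p in model.lineages])
fits, summary = anchor_trajectory_report(ds, model, "IL11")
print(summary[["path", "p", "anchor_associated"]].to_string(index=False))
cells = [model.cell_ids[i] for i in model.lineage_cells(1)]
module = anchor_module(ds, cells, "IL11")
print(len(module.genes), "genes correlated with IL11 at FDR<0.2")
```

prints

```
['transitional_AT2>AT1_intermediate>AT1', 'transitional_AT2>aberrant_intermediate>aberrant_basaloid']
                                                      path            p  anchor_associated
                   transitional_AT2->AT1_intermediate->AT1 6.433136e-01              False
transitional_AT2->aberrant_intermediate->aberrant_basaloid 2.411673e-22               True
103 genes correlated with IL11 at FDR<0.2
```

i.e. two lineages are recovered from the origin, the anchor's expression
is associated with pseudotime only on the aberrant branch, and the
trajectory-restricted co-expression screen retains 103 genes (the 40
planted module genes plus correlates admitted at the 0.2 FDR level).

The same workflow is scriptable from the shell:

```bash
scfibro simulate --seed 7 --out data/
scfibro run --ref data/ --seed 7 --out results/
```

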