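# Methods

This note documents the models, numerical choices and known limitations of
`scfibro`. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from outside the package.

## Statistical primitives

- **Spearman correlation** is the Pearson correlation of mid-ranks
  (average ranks on ties); the two-sided p-value uses the t-approximation
  with n−2 degrees of freedom. The exact permutation null is used only in
  tests (n ≤ 10). Rank statistics make all downstream screens invariant to
  per-cell monotone rescalings of the normalized layer.
- **FDR** is Benjamini–Hochberg step-up throughout; the module screen uses
  q < 0.2, pathway over-representation q < 0.1, marker significance
  q < 0.05. BH assumes positive regression dependence; scRNA-seq gene–gene
  dependence can push the realized false-discovery proportion somewhat
  above the nominal level (see Limitations).
- **Hypergeometric enrichment** is the exact upper tail P(X ≥ k), computed
  in log space; **Mann–Whitney** uses the exact distribution when both
  samples have ≤ 10 untied observations, otherwise the tie- and
  continuity-corrected normal approximation; the **Kolmogorov–Smirnov**
  p-value is asymptotic at effective size nm/(n+m). Each result records
  the exact variant used in its `method` field.

## QC and preprocessing

Cells must show ≥ 200 detected genes, ≥ 500 UMI,
log10(genes)/log10(UMI) > 0.8 and a mitochondrial fraction < 30%
(case-insensitive "mt-" prefix); genes must be detected in ≥ 3 cells.
The gene filter runs first, then the cell filters, and the filter is
idempotent. Normalization is ln(1 + 10⁴·count/total) per cell; natural
log and the 10⁴ scale are conventions — every downstream statistic that
matters (Spearman, Mann–Whitney, KS) is invariant to this monotone choice.
HVGs are ranked by within-mean-bin z-scored dispersion (20 equal-count
bins); PCA is centered with a deterministic sign convention (largest
loading positive).

## Trajectory model

Lineages are paths from the origin cluster to each leaf of the Euclidean
minimum spanning tree over cluster centroids in a 2-D embedding, with MST
ties broken lexicographically so inference is fully deterministic.
Pseudotime is arc length from the origin centroid to the cell's orthogonal
projection onto the piecewise-linear centroid curve. This replaces
simultaneous principal curves with a simpler, testable geometry; on the
synthetic bifurcation the within-branch Spearman correlation between
pseudotime and true latent time is ≈ 0.99, and rank-based downstream
statistics do not benefit from curve smoothing.

Pseudotime–expression association fits normalized expression on a cubic
B-spline basis (df = 5 basis functions, interior knots at pseudotime
quantiles, plus intercept) by least squares and tests the spline against
the intercept-only model with an F-test. Gaussian errors on the log
scale are an approximation; the type-I error of the test is calibrated by
simulation (rejection rate at α = 0.05 within [0.03, 0.07] over 2000 null
replicates at n = 200). Per-lineage p-values are BH-adjusted across
lineages and lineages with q < 0.05 are flagged anchor-associated.

## Anchor co-expression module

Over the cells assigned to the trajectory of interest, candidates are the
genes detected in ≥ 5% of selected cells (the detection floor excludes
all-zero vectors for which rank correlation is undefined; it is
configurable). Each candidate is Spearman-correlated with the anchor, BH
is applied across candidates, and genes with q < 0.2 are retained. The
enrichment universe for pathway over-representation is the candidate set —
a conditional-on-testing background, which differs from web-tool defaults
that use a whole-genome background. Network edges are all-pairs Spearman
correlations among module ∪ anchor; the default edge threshold 0 exports
the complete graph.

## Label transfer

A deliberately transparent stand-in for anchor-based integration: HVGs are
chosen on the reference restricted to shared genes, both datasets are
standardized by the reference per-gene mean/sd and projected onto the
reference's randomized-SVD loadings (30 PCs), and each query cell takes
the majority label of its 15 nearest reference neighbors (ties broken by
summed inverse distance). On batch-paired simulations at the default
batch scale (per-gene log2 shifts ~ N(0, 0.25)) accuracy against hidden
truth is ≈ 0.97, and the Jaccard QC of transferred-versus-truth markers
(mean diagonal ≥ 0.5) mirrors the workflow's own quality check.

## Preranked GSEA and scoring

The enrichment score is the classic weighted running sum: hits add
|stat|^w normalized by the set's total |stat|^w (w = 1), misses subtract
1/(N − N_hit); ES is the signed maximum-magnitude deviation (the positive
deviation wins an exact tie). The null is gene-permutation: random
same-size gene sets, 10⁵ by default, sampled in vectorized batches; NES
divides ES by the mean |null ES| of matching sign, and
p = (1 + #{|null| ≥ |ES|, matching sign}) / (1 + #matching), floored at
1/(n_perm+1). The leading edge comprises set members at or before the ES
extremum (at/after it for negative ES). The ranking statistic for
pseudobulk contrasts is a Welch t on log2(CPM+1); any externally computed
ranking (e.g. a regression Wald statistic) can be supplied as a 2-column
TSV via the CLI.

Module scores are the mean normalized expression of the set minus that of
expression-matched controls: genes are binned into 24 equal-frequency bins
by mean expression and each set gene draws 100 controls from its bin
(excluding set genes; all bin genes when `n_ctrl=None`). Scores are
deterministic given the seed and centered near zero for random sets.

## Synthetic data: what it emulates and what it does not

Counts follow NB(mean = s_i·μ_gi, Var = μ + μ²/θ) with a single shared
dispersion θ = 2, log-normal library sizes (cv 0.3) and log-normal
baseline means (ln-mean ln 0.5, sd 1), giving ~60% zeros and QC survival
of ~95% at the method's fixed depth thresholds. Five clusters lie on a
bifurcating latent trajectory (origin t∈[0,0.2]; two branches with
intermediate t∈[0.2,0.6] and terminal t∈[0.6,1.0] states, 20% of cells
each). The anchor's log-mean rises linearly with t on the aberrant branch
only (slope 2·ln 2); each of the 40 module genes and the anchor load a
per-cell N(0,1) factor with loading 1.27 in disease-condition cells and 0
in controls. The loading was calibrated once, by Monte-Carlo at large n,
so the empirical anchor–module Spearman among disease branch-B cells is
≈ 0.45. Cluster-specific DE genes (20 per cluster, 4-fold) give clusters
identifiable signatures; signal genes (anchor, module, DE) have a baseline
floor of 0.3 mean counts so their effects are detectable at the simulated
depth. The gene universe is 5,000 genes so that the 41 factor-loaded genes
are a realistically small fraction of the transcriptome; with a much
smaller universe the factor visibly sways total UMI and library-size
normalization induces spurious anchor–background rank correlations that
real ~20k-gene data does not show at this strength. The default embedding
is the simulator's branch-unfolded (t, ±branch offset) layout with
Gaussian noise (sd 0.03), separating trajectory-algorithm behavior from
upstream dimensionality-reduction noise; PCA-of-counts can be used
instead. Paired datasets share gene parameters and differ by independent
per-gene log2 batch shifts (sd 0.25); the query's labels are hidden for
transfer benchmarks.

Not emulated: gene length/GC bias, doublets, ambient RNA, UMI saturation,
multi-factor module structure, cell-cycle covariates. Passing tests
demonstrate correct recovery under the stated generative model, not
robustness to those artifacts.

## Known limitations

- **Module FDP slightly above nominal.** At FDR 0.2 the realized
  false-discovery proportion of the module screen against the planted
  module averages ≈ 0.24: beyond the BH-expected 0.20, cluster-DE genes
  genuinely correlated with the anchor through the shared trajectory
  contribute ≈ 0.04, and a small residual depth-composition rank artifact
  ≈ 0.02. These are properties of Spearman screens on normalized counts,
  not implementation defects.
- **KS contrast under dependence.** The two-sample KS test treats the
  module's per-gene correlations as independent draws. Because module
  genes share the latent factor (and every correlation shares the anchor's
  realized ranks), a random split of the same cells yields correlation
  vectors with a common per-half shift, and the KS null p-values are
  anti-conservative (mean ≈ 0.26 instead of ≈ 0.55 for uncoupled genes,
  which are calibrated). The disease-versus-control contrast it is used
  for is far stronger than this bias (p < 0.01 in 50/50 replicates), but
  borderline KS p-values on coupled gene sets should not be read at face
  value.
- **Decile monotonicity of the anchor trend** is a large-sample property:
  with ~40 cells per decile the anchor's factor noise dominates the
  per-decile trend step; the property test verifies it at 20,000 cells.
- The trajectory model assumes clusters order linearly along branches in
  the embedding; it has no branch-assignment uncertainty and no
  between-lineage differential tests.
- DESeq2-style shrinkage is out of scope for the ranking statistic; the
  Welch t on log2(CPM+1) is monotone-equivalent for GSEA purposes at the
  simulated effect sizes, and external rankings are accepted.
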