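# Methods

## Scope and model of the workflow

`sccompare` treats the standard scRNA-seq pipeline as a sequence of
stages, each of which has two documented algorithmic variants in the
field's mainstream toolkits. Every stage is implemented from its
mathematical definition (not by wrapping either toolkit), with the
variant choice an explicit parameter. A pipeline run is therefore a point
in a small configuration space, and the package's purpose is to measure
distances between such points with per-stage concordance metrics.

Notation: `X_ig` is the UMI count of gene *g* in cell *i*;
`S_i = (Σ_g X_ig)/sf` with scale factor `sf = 10,000`;
`Y_ig = log(X_ig/S_i + 1)` (natural log by default, base configurable).

## Stage definitions and numerical choices

**Filtering.** Cells with fewer than `min_genes_per_cell` detected genes,
fewer than `min_umi` total counts, or mitochondrial percentage above
`max_mito_pct` are removed first; genes detected in fewer than
`min_cells_per_gene` remaining cells are removed second (single pass,
cell filter before gene filter). Mitochondrial genes are flagged by
identifier prefix (default `MT-`); annotation-database lookup is out of
scope. UMI filtering is a plain threshold — knee-point detection is not
implemented. An all-cells-removed outcome raises an error carrying each
sub-filter's casualty count.

**Normalization.** CP10K + log1p as above. The invariant
`Σ_g expm1(Y_ig) = sf` per cell is exact by construction and asserted in
tests to 1e-6 relative.

**HVG, binned-dispersion flavor.** Dispersion `d_g = σ²_g/μ_g` is
computed on `Y` (variance/mean, not sd/mean; a flag is deliberately not
offered since the variance form is what the mirrored implementations
use); `log d_g` is z-scored within bins of mean expression. Binning is
equal-width over the range of `μ_g` by default with an equal-frequency
(ranked) alternative behind the `binning` flag, because "binned by mean
expression" admits both readings. The within-bin sd uses the actual bin
occupancy minus one as its denominator so that unequal bins are
well-defined; a single-gene bin carries no spread information and its
gene keeps z = 0. Zero-mean and zero-dispersion genes are excluded from
z-scoring and can never be selected. Selection is top-n by z (ties to
the lower gene index) or by mean-window + dispersion thresholds
(defaults 0.0125 ≤ μ < 3, z ≥ 0.5).

**HVG, loess-VST flavor.** Works on raw counts. A loess curve (tricube
weights, span 0.3, degree 2, unweighted observations — the span is a
package constant since no reference value exists) of `log₁₀ σ²_g` on
`log₁₀ μ_g` yields a predicted variance per gene; counts are
standardized with their own mean and the predicted sd, clipped **above**
at `sqrt(n_cells)` (the mirrored flavor's clip; `clip=None` disables it,
and only genes with standardized values above the clip are affected);
genes are ranked by `Σ_i z²_ig/(n−1)`. The loess is a direct local
weighted polynomial fit evaluated at the data points; no installed
package provides degree-2 loess, and the local quadratic matters because
the mean-variance trend is curved — on exactly collinear points the fit
reproduces the line, which the tests exploit as an analytic fixture.

**Scaling/regression.** Optional per-gene OLS residuals on covariates
(with intercept) come first, then centering to mean 0 and scaling to
unit (population) variance, then upper clipping at `clip_max`
(symmetric clipping behind a flag). Zero-variance genes become all-zero
columns and are flagged rather than erroring. The `scanpy_like` preset
regresses on per-cell total counts and mitochondrial percentage.

**PCA.** Exact SVD of the column-centered matrix; variance explained is
each eigenvalue over the sum of *all* eigenvalues. Component signs are
fixed by making the largest-|loading| entry positive, so two runs can be
compared without the eigenvector-sine metric absorbing arbitrary sign
flips. `K` defaults to 50 and is clamped to the rank (with a warning)
and to the HVG count at desk scale.

**KNN/SNN.** KNN is exact (Euclidean in PC space, ties to the lower cell
index, self node included and always first) — the approximate searches
used by the toolkits at scale are emulated by their exact limit, which
is also what both use below a few thousand cells. The Jaccard SNN scores
every pair sharing at least one of their k-sized neighbor sets as
`|N_i ∩ N_j|/|N_i ∪ N_j|` and zeroes weights strictly below the prune
threshold (default 1/15); pairs sharing no member have weight 0 anyway,
so restricting to co-membership pairs changes nothing. The union SNN is
the unweighted symmetrized KNN digraph minus self-loops, giving every
node degree ≥ k−1.

**Louvain.** Both variants iterate seeded-shuffle node sweeps and graph
aggregation until no node moves. Quality forms (package constants):

* `local_moves_scaled`: `Q = Σ_c [w_c − γ·K_c²/(4W)] / W` — the standard
  resolution-scaled modularity normalized by total weight; move
  candidates are restricted to the communities of a node's neighbors;
  sweeps per level are capped (default 10).
* `all_moves_expected`: `Q = Σ_c [w_c − γ·K_c²/(4W)]` — the same
  configuration-null penalty, unnormalized; candidates are every
  nonempty community plus one empty community (an escape from local
  optima); no sweep cap.

`w_c` is within-community weight (each edge once, self-loops included
after aggregation), `K_c` the summed strengths, `W` the total weight of
the **whole** network — components are optimized independently (and
label-offset) but share the global `W`, since a component-local `W`
would multiply the effective resolution by the number of components.
Ties between equally good moves go to the first candidate in scan order;
a move is only accepted on a strict (>1e-12) gain, which makes every
accepted move increase the quality (asserted in the loop). The optimizer
was checked against exhaustive partition search on 8-node fixtures and
against igraph's multilevel implementation on planted-cluster graphs.
Leiden is not implemented (the toolkits' Leiden paths share one backend
and agree); externally computed labels can be injected instead.

**Differential expression.** One-vs-rest Wilcoxon rank-sum per gene:
average ranks over all cells, `z = (W − n₁(N+1)/2)/σ_W` with the tie
term `Σ(t³−t)/(N(N−1))` subtracted from the variance iff tie correction
is on, two-sided normal p, no continuity correction (matching both
mirrored implementations), p = 1 when `σ_W = 0`. Four logFC formulas
(base 2 by default, base-e flag) as in the README table; the expression
fraction `pct` uses raw-count detection (`X > 0`, equivalently `Y > 0`)
and the filter uses max-over-groups semantics (an either-group flag
exists). Adjustment multiplies by the per-cluster gene count
(`m = #genes`); the p threshold applies to the adjusted value. The rank
test is always computed for all genes and filtering only flags rows, so
unfiltered statistics stay inspectable; prefiltering before the test is
available as a flag.

## Concordance metrics

Neighborhoods for SNN metrics are nonzero-weight neighbors excluding
self; cells with zero degree in both graphs score Jaccard 1 and ratio 0
(identical emptiness is agreement), and infinite one-sided ratios are
excluded from the median. Per-cell neighborhood Jaccard respects the
degree-ratio upper bound `min(d₁,d₂)/max(d₁,d₂)`, asserted per cell in
tests. PC loading differences restrict to genes shared by both runs'
HVG sets, sign-align each PC pair by dot-product sign, average absolute
differences over PCs 1–3 (absolute rather than signed differences — a
signed mean would cancel); eigenvector sine uses
`sin = √(1 − cos²)` with `cos = |v₁·v₂|/(‖v₁‖‖v₂‖)`. The CCC uses
population moments (the original convention; a sample-moment flag
exists). Jaccard of two empty sets is 1. ARI is the standard
permutation-model form (delegated to scikit-learn). DE tables are keyed
by (cluster, gene); when the two runs' labelings differ, run-b cluster
ids are first mapped onto run-a ids by maximum-weight matching of the
overlap counts, and unmatched clusters get fresh ids so keys cannot
collide.

**Cluster alignment.** Run-1 clusters are ranked by decreasing size;
each run-2 cluster targets the rank of its maximum-Jaccard run-1 partner
(exact Jaccard ties go to the lower-ranked partner); run-2 clusters
contending for one partner are ordered by decreasing size. The
implementation realizes this as a stable sort on (target rank, −size),
which reproduces the increment/decrement conflict loop of the reference
pseudocode on all fixtures. Zero-overlap run-2 clusters are dropped with
a warning. Color matching is maximum-weight bipartite matching on
overlap counts (scipy's assignment solver); unmatched clusters receive
fresh colors.

## Synthetic data

Counts are Gamma–Poisson (negative binomial) draws — the canonical UMI
count model: gene means are Gamma(0.8, 2.5) (sparse baseline ≈ 2
counts/cell), each of the equally sized clusters shifts a disjoint 10%
of genes by a log-scale effect of 1 by default, per-cell library factors
are log-normal (σ = 0.35, mean 1), and dispersion is 2 (variance
μ + μ²/2). About 3% of genes carry a mitochondrial name prefix. Read
downsampling is binomial thinning of the counts, `X → Binomial(X, p)`,
which is the count-level distribution induced by uniform read
subsampling; cell downsampling is a uniform row subsample preserving
order. Thinning is multiplicative in expectation and composes
(`p₁` then `p₂` ≍ `p₁p₂`), both verified by moment tests.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, read-level sequencing error, non-discrete cluster structure,
or gene–gene correlation beyond cluster membership. Passing tests
therefore demonstrate correctness of the stage implementations and the
direction/relative size of divergences, not the magnitudes those
divergences take on any real dataset.

## Harness

Integration tests and examples run at desk scale — 240 cells × 200
genes, three clusters, marker effect 2.0 on 20% of genes — with filter
thresholds matched to that scale (≥30 genes/cell, ≥50 UMIs, mito ≤ 50%)
and 60 HVGs; these sizes were chosen once as the smallest at which every
stage (including 50-PC PCA and k = 20 graphs) is non-degenerate.

The downsampling sufficiency rule: for each grid fraction the preset is
rerun on downsampled counts and compared with the full-size run; DE is
computed with the full-size run's cluster labels transferred onto the
surviving cells so marker statistics refer to identical clusters. The
reference variability `v_ref` defaults to the cross-preset comparison at
full size; the sufficiency fraction per metric is the smallest grid
fraction whose value is at least as good as `v_ref` within a 5% margin,
direction-aware (≥ 0.95·v_ref for similarity metrics, ≤ 1.05·v_ref for
dissimilarity metrics) — the margin is relative to `v_ref` since no
absolute convention exists, and the direction of every metric is fixed
in `SIMILARITY_METRICS`/`DISSIMILARITY_METRICS` so results are
auditable. The default grid is {0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0}
with 0.01 as the floor. Downsampled-data filter thresholds are exposed
but not auto-tuned (no objective is defined for the tuning).

Seed-sensitivity studies freeze everything upstream of one nominally
stochastic stage (`knn`, `louvain`, `embedding`) and rerun it per seed.
Exact KNN is seed-free by construction, so its reports are the identity
baseline; the 2-D embedding stage defaults to the first two PCs — a
deterministic stand-in consumed by the embedding-KNN metric — and an
externally computed embedding (e.g. UMAP) can be passed into
`run_pipeline` instead, since nonlinear-embedding internals are out of
scope.

## Known limitations

* Dense desk-scale numerics throughout (no implicit-centering sparse
  PCA, no approximate KNN); tens of thousands of cells are out of reach.
* The Wilcoxon p is purely asymptotic; at very small group sizes it
  deviates from the exact null by design (documented in tests:
  p ≈ 0.0495 asymptotic vs 0.1 exact on 3-vs-3).
* `scanpy_like` HVG thresholds can select very few genes on tiny
  matrices; the harness clamps the PC count and errors below 3 HVGs.
* Marker-filter presets approximate each toolkit's defaults at one point
  in time; version drift within a toolkit is represented only by the
  v4/v5 logFC/filter presets.
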