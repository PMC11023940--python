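# Methods

## Problem setting

Bulk RNA-seq measures a transcript mixture over an unknown composition of
cell types. Reference-based deconvolution estimates that composition: given
a signature matrix **C1** (genes × cell types, per-type mean expression
derived from annotated single cells) and a bulk profile *y*, solve for the
weight vector *w* ≥ 0, Σw = 1 that best explains *y ≈ C1·w*. deconvbench
implements the machinery needed to *benchmark* this operation end to end:
simulation of ground-truth mixtures, reference construction, a family of
regression solvers, a metric suite, and a consensus estimator for use on
real data.

## Pseudo-bulk simulation

Ground truth requires simulated bulks. The single-cell input is split in
half, stratified by cell type: the training half yields the reference, the
testing half is the sampling pool, so reference and mixture never share
cells. Training-fraction rounding is `floor(n_type * fraction)` per type
(remainder to test), deterministic given the seed.

Two generation modes:

* **Mode 1** draws `c` cells uniformly with replacement from the whole
  pool, `n` times. Samples concentrate tightly around the pool composition
  — useful as an easy baseline, unrealistically homogeneous as a benchmark
  (the diagnostics module exposes this as a high median pairwise sample
  correlation).
* **Mode 2** first draws target proportions per sample, controlled by the
  proportional-variance parameter `p`:
  * `p < 0`: independent uniform(0.01, 0.99) draws, normalized — maximal
    spread;
  * `p > 0`: integer weights uniform on {1, …, 1+2⌊p⌋}, normalized — small
    `p` gives near-homogeneous mixtures, large `p` approaches the uniform
    case. Non-integer `p` floors with a warning; `p = 0` is rejected
    because the sign convention leaves it undefined.
  * `sampleCT` set: each type falls with probability ½ into a near-zero
    mode (normal, mean 0, SD 1e-4) or a kept mode (normal, mean 1, SD
    `p`); absolute values per draw, then normalization. At least one type
    is forced into the kept mode by redrawing the assignment. This
    emulates tissues where the signature lists more types than the sample
    contains.

Target proportions become integer cell counts by largest-remainder
rounding (ties to the lowest type index), so the recorded ground truth is
exactly `counts / c` — rational, row sums exactly 1 — and all stochastic
error comes from which cells are drawn. Aggregation defaults to summing
raw counts (a bulk is a sum of transcripts); per-cell mean is available
and differs only by a per-sample scale factor.

## Reference artifacts

From the training half: **C0** (the raw counts plus metadata), **C1**
(per-type arithmetic means), **refVar** (per-type gene-wise sample SD,
ddof = 1; a single-cell type gets 0 with a warning), and **C2** (ranked
marker lists). Marker discovery library-normalizes each cell to 1e4
counts, log1p-transforms, and runs one-vs-rest tests per type (Wilcoxon
rank-sum by default, Welch's t as the alternative). Genes must be
expressed in ≥ `min_pct` (default 0.1) of in-group cells and show a
natural-log fold change of de-logged means ≥ 0.25; Benjamini–Hochberg
correction is applied over the *full* gene family (non-candidates enter
at p = 1 — correcting only within the prefiltered candidates inflates
false positives under a null dataset), with significance at adjusted
p < 0.05. Two marker sets can be intersected (`marker_overlap`),
preserving the first set's rank order; empty intersections warn rather
than fail.

### Rank-sum p-values

For tie-free samples with combined n ≤ 30 the exact null distribution of
the Mann–Whitney U statistic is used (the convention of the standard
implementations); larger or tied samples use the normal approximation
with midranks, tie-corrected variance and a 0.5 continuity correction.
The exact branch matters: at extreme size imbalance (e.g. 1 vs 3) the
normal approximation is off by > 0.1 in absolute p.

## Preprocessing grid

Ten normalizations (none, column, row, mean, column z-score, global
min-max, CPM, TMM, median-of-ratios, quantile) × three transformations
(none, ln(1+x), √x) × two orders (normalize-first / transform-first),
applied independently to the bulk matrix and C1. Choices worth noting:

* `log` is ln(1+x) — the single-cell convention of the marker-finding
  workflow; no base-10 variant.
* TMM: reference column = the one whose upper quartile of
  library-scaled counts is closest to the mean upper quartile; trim
  fractions 0.3 (M) and 0.05 (A), the canonical defaults; factors are
  precision-weighted trimmed means of M values, rescaled to geometric
  mean 1; output is counts per million of the effective library.
* Row normalization divides by row sums; zero rows pass through as zeros
  with a warning.
* Transform-after-z-score would feed negatives into log/sqrt and is
  rejected with a message saying why; likewise the single-cell-specific
  external normalizers (SCTransform, scran, scater, Linnorm) and the vst
  transformation raise a clear out-of-scope error.

## Solvers

All solvers share the projection step: negative coefficients truncated at
zero, then renormalized to the simplex; an all-zero solution returns the
uniform vector with a warning (never a silent NaN). Per-sample solves are
independent.

* **ols** — unconstrained least squares (`numpy.linalg.lstsq`).
* **nnls** — Lawson–Hanson active-set NNLS (`scipy.optimize.nnls`).
* **rlr** — iteratively reweighted least squares with Huber weights,
  k = 1.345 (statsmodels RLM).
* **ridge / lasso / elastic_net** — penalized least squares via
  scikit-learn coordinate descent; penalties default to weak values
  (α = 1e-4) so noiseless mixtures are recovered essentially unbiased
  while retaining shrinkage against collinearity; `l1_ratio` defaults to
  0.5 for the elastic net.
* **dwls** — dampened weighted least squares. Initialize at the NNLS
  solution; re-weight genes by 1/max((C1·ŵ)², ε) so low-expressed genes
  (the signal of rare types) are not drowned out; cap the weight ratio at
  2^d; iterate weighted NNLS to a fixed point (tolerance 1e-6 on the
  normalized solution, max 100 iterations). The dampening exponent d is
  selected once per sample from the grid {1…14} by minimizing the mean
  coefficient variance of the weighted solution across 100 bootstrap
  resamples of genes (weighted ordinary least squares inside the
  selection loop, for speed); both grid and resample count are
  hyperparameters. On noiseless mixtures re-weighting leaves the optimum
  unchanged, so DWLS recovers the truth exactly.

Solvers are sklearn-style estimators (`fit(reference)` /
`predict(bulk)`, fitted attributes with trailing underscores,
`get_params`/`set_params`), so they compose with sklearn tooling;
`solve_sample` and `run_methods` are thin functional wrappers.

### Consensus

The consensus is the per-sample, per-type arithmetic mean of the member
solvers' estimates — default members (dwls, rlr, nnls), the native
stand-ins for the published DWLS/EpiDISH/FARDEEP trio, chosen for the
same reasons (accurate, stable, always produce output) — renormalized per
row because a member's uniform fallback can break exact row sums.
Agreement diagnostics: cross-method SD per entry (population SD, ddof = 0,
over the fixed member set) and the mean pairwise Pearson correlation of
the flattened member matrices.

## Evaluation

Nine metrics: Pearson, Spearman, RMSE, weighted RMSE, MAE, Euclidean
distance, distance correlation, cosine similarity, R² (truth-referenced,
directional). Default scope flattens samples × types into one vector;
per-sample and per-cell-type means are available because errors often
concentrate in specific types. Correlations on constant input are
undefined and reported as NaN sentinels, never coerced to 0.

Weighted RMSE upweights rare types: w_k ∝ 1/(m_k + 1e-6) with m_k the
mean true proportion of type k, normalized to sum 1; the score is
√(Σ_k w_k · mean_i(pred−truth)²). When all types share the same mean true
proportion the weights collapse to 1/k and the score equals plain RMSE.
This inverse-mean form is this package's declared convention — the
quantity is named in the literature without a printed formula.

For purified (single-type) samples the background-prediction score is the
log loss −ln(clip(p̂[true type], 1e-15, 1)): 0 for a perfect one-hot
prediction, ln k for a uniform one, ≈ 34.5 at the clip.

Without ground truth, `agreement_analysis` reports the pairwise Pearson
matrix over flattened proportion estimates plus an average-linkage
clustering order (distance 1 − r), so methods that agree appear adjacent
in the heatmap.

## Synthetic data generator

Counts are negative binomial with variance mean + φ·mean² (φ = 0.5
default), per-gene base means log-normal (median 0.5 counts/cell, log-SD
1), which reproduces the heavy-tailed mean distribution and
mean–variance overdispersion of UMI data. Each type gets 25 designated
markers (default) whose mean is multiplied by `marker_fold` (default 4);
`marker_fold = 1` is an exact null. Cells are assigned round-robin to 3
donors. Defaults — 2000 genes, 4 types, 300 cells/type — are the
desk-scale study conditions used throughout the tests and the acceptance
script; they are deliberately small enough to run in seconds yet large
enough that the solver family separates cleanly from chance.

`inject_batch_effect` multiplies each gene by a log-normal factor
(log-SD σ) and re-rounds, emulating a multiplicative platform shift
between reference and bulk. Applying it to the reference half only is the
desk-scale analogue of cross-reference deconvolution and reliably
degrades accuracy.

What the generator does **not** emulate: doublets, ambient RNA,
donor-correlated expression shifts (donors are exchangeable), gene–gene
correlation beyond the type structure, zero inflation beyond the NB, and
length/GC biases. Passing benchmarks on this generator therefore
demonstrates correctness of the machinery and qualitative orderings
(e.g. batch effects hurt; mode-1 samples are too similar), not absolute
performance on real tissue.

## Numerical and degenerate-input choices

* Gene-id matching is exact string equality after whitespace strip; no
  alias resolution. Duplicate gene rows are summed with a log line.
* Mitochondrial genes are identified by a configurable id prefix
  (default "MT-", case-insensitive); QC fractions use raw counts.
* Proportion rows must sum to 1 within 1e-8 at validation; simulated
  truth is exact by construction.
* Largest-remainder ties break to the lowest type index; quantile
  normalization uses ordinal ranks (stable sort), making output columns
  share sorted values exactly.
* Matrices are genes-in-rows everywhere; MatrixMarket orientation is
  asserted from companion index-file lengths, never guessed from shape.

## Scalability logging

`run_methods` and the benchmark runner record wall-clock time, CPU time
and peak RSS (`ru_maxrss`, where the platform exposes it; missing values
are recorded as missing, not zero) per stage, written into the run
manifest together with a sha256 inventory of every artifact. A rerun
with identical config and seed reproduces all TSV artifacts
byte-identically; all randomness flows from `numpy` `SeedSequence`
children of the single run seed.

## Known limitations

* Only the regression family is implemented natively; single-cell-input,
  marker-only and unsupervised methods are out of scope (the solver
  registry is open for plug-ins).
* TMM/median-ratio require ≥ 2 columns; single-sample bulks must use
  column-wise or global normalizations.
* The DWLS dampening-selection heuristic is a simplified form of the
  published grid search; it is stable in practice but its selected
  exponent is not guaranteed to match other implementations.
* No HDF5/loom IO, no sparse in-memory path; dense matrices cap the
  practical size at roughly 10⁴ genes × 10⁵ cells on a workstation.
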