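# Methods

This note records the models, numerical choices and open design decisions
behind `keygenes`, and what the synthetic benchmarks do and do not show.

## Model

Identity scoring is multinomial logistic regression with an L1 penalty.
For classes k = 1..K, features j = 1..p and samples i = 1..n:

    minimize over W (K x p), b (K):
        -(1/n) Σ_i log softmax(W x_i + b)[y_i]  +  λ Σ_{k,j} |W_kj|

Inputs x are log₂(CPM+1), standardized per gene to mean 0, sd 1 using
**training-set** statistics only; the same means/scales are reused verbatim
for test samples, so a test profile is interpreted strictly on the training
scale. Identity scores are the fitted class probabilities; they are the
natural quantity matching all behaviours expected of such a score (range
[0, 1], one dominant class for clean samples, informative second-best hits,
and mixed-tissue samples splitting their mass between two classes). The
score is *relative to the training classes*: a tissue absent from the
training set still receives a best hit, just a weak and unstable one, which
is why flexible training-set composition matters (see `compose_training_set`
and example 04).

The full symmetric softmax parameterization is used (one coefficient row per
class, penalty over all rows, intercepts unpenalized), matching the default
multinomial mode of the R package glmnet that popularized this model. Two
consequences worth knowing:

* intercepts are identified only up to a common shift; the solver starts at
  zero and never enters the flat direction, so they come out sum-zero;
* for K = 2 the penalized coefficients are identified only through their
  difference (any split w₁ − w₂ = δ with |w₁|+|w₂| = |δ| is optimal);
  diagnostics on 2-class problems should therefore compare probabilities or
  coefficient differences.

## Penalty path and model selection

The path has 100 log-spaced values from λ_max (the smallest penalty nulling
all coefficients, computed from the score equations at the intercept-only
optimum) down to 10⁻⁴·λ_max; both the length and the floor are
configurable. λ is selected by k-fold cross-validation (default 10) on mean
held-out multinomial deviance, with per-fold fits over the whole path.
Folds are assigned per class, round-robin after a seeded shuffle: classes
with ≥ k samples are exactly stratified, smaller classes (down to single
samples, which the API allows but warns about) are spread over a random
subset of folds. Selection rules: `min` (default) or `one_se` (largest λ
within one standard error of the minimum). Deviance for a held-out sample
of a class absent from the fold's training part uses a probability floor of
1e-10. On well-separated data the deviance decreases monotonically along
the path and `min` selects the path floor; this is expected, not a defect —
the model at the floor is the maximally inclusive sparse fit, and on the
synthetic benchmark it is the point where the active set snaps onto the
planted marker set.

The classifier genes of a run are the features with nonzero coefficients at
the selected λ. The feature space is recomputed per query (candidate pool ∩
test genes ∩ training genes), so classifier-gene sets legitimately differ
between test sets; `ClassifierGeneSet.intersect` supports comparing runs.
The active-set size is not exactly monotone along the path — coordinates
occasionally drop out and re-enter (ordinary L1-path behaviour) — so
downstream code must not assume monotonicity.

## Solver

The path is fit by FISTA (accelerated proximal gradient) with monotone
restarts and a fixed step 2n/σ_max(X̃)², where X̃ is the design including the
intercept column — a safe bound because the softmax-loss Hessian is
dominated by (1/2)XᵀX/n. A sequential strong rule screens features
(a feature enters the subproblem when its gradient magnitude at the previous
solution exceeds 2λ_t − λ_{t−1}); full KKT conditions are then verified on
all features and violators re-enter, so screening never changes the
solution. The inner loop is numba-compiled when numba is importable, with a
numpy implementation of the same iteration as fallback. Warm starts run
down the path. Convergence is declared when the coefficient update falls
below `tol` (relative to the largest coefficient); cross-validation fold
fits use a looser tolerance (1e-4, ≤ 300 iterations) than the final
full-data fit (1e-6, ≤ 3000) since fold coefficients only feed the deviance
curve. Fully sparse solutions snap to the exact intercept-only optimum
(centered log class frequencies), which also makes "scores equal class
priors under the maximal penalty" exact rather than approximate. The test
suite validates the solver at fixed penalties against scikit-learn's saga
optimizer to 1e-6 (observed ~1e-8).

## Normalization

TMM is a literal implementation of the weighted-trimmed-mean-of-M-values
procedure: reference sample by the 75th-percentile rule; per pair, genes
with zero counts in either member are excluded (no pseudocounts); trim 30%
of M-values and 5% of A-values from each tail (rank-based, average ranks on
ties); weight surviving M-values by inverse delta-method binomial variances;
factors rescaled to geometric mean 1. The suite cross-checks factors
against both an independently coded brute-force transcription (1e-8) and
Bioconductor's edgeR via Rscript (1e-10, observed agreement to machine
precision). The detection filter (keep genes with ≥ 4 reads in ≥ 1 sample —
the boundary count of exactly 4 is kept) is applied *before* factor
computation by the CLI; both orders are possible through the API, as the
published procedure does not pin this down.

The variability measure for the candidate pool defaults to variance of
log₂(CPM+1); plain CPM variance is available (`variance_cpm`) because the
choice is not pinned down either and can change the selected pool. Ties are
broken lexicographically by gene ID for reproducibility.

## Cross-platform bridge

The mapping from array intensity to training CPM is not described in any
detail by the original tool, so three candidate reconstructions are
provided; all are per-sample and anchored on housekeeping genes (panel ∩
both datasets, training CPM ≥ 1 in ≥ 1 sample; the threshold is
configurable, the published description gives none):

* `affine` (default): least-absolute-deviations line in log₂(x+1) space
  from the sample's housekeeper intensities to the training-mean
  housekeeper log-CPM profile, solved exactly as a linear program (HiGHS).
  Exact LP solutions make the map idempotent on the affine family: data
  already on the training scale passes through unchanged, and applying the
  bridge twice is a no-op to ~1e-10.
* `offset`: gain fixed at 1, offset = median housekeeper log-ratio.
* `quantile`: monotone interpolation of housekeeper quantiles.

Fewer than 10 usable housekeepers is a hard error. Note that measurement
noise on the intensity side attenuates the fitted gain (regression
dilution); classification is robust to this because scores depend on
between-tissue contrasts, not absolute calibration.

## Synthetic data

`SimulationTruth.default` emulates the structure of a two-trimester fetal
organ atlas at desk scale: 8 tissues, 2 stages, 2000 genes, 20 disjoint
markers per tissue at 32-fold elevation, negative-binomial counts with
dispersion 0.1, lognormal baseline means scaled to ~10⁶ reads per sample
with per-sample library factors in [0.7, 1.3], and 300 designated
housekeeping genes with reduced biological variance (σ = 0.4 in log space).
Shared markers across two tissues can be planted (`n_shared_markers`) to
emulate multi-class barcode genes. The microarray generator applies an
affine distortion of log₂ CPM plus Gaussian noise, exponentiates, and
subsamples probes while always retaining housekeepers.

What passing the synthetic benchmarks shows: the pipeline recovers planted,
well-separated signals through the full normalization → selection → fit →
scoring chain, on both platforms, deterministically. What it does not show:
performance under realistic transcriptome-wide correlation, overlapping
marker programs, batch effects, or cellular heterogeneity — the generator
plants independent NB genes and makes no attempt to mimic real covariance.
Identity scores of 1.000 on the fixture reflect that idealization, not
expected field performance.

## Degenerate inputs and tie-breaks

Duplicate gene rows on input are collapsed (sum for counts, mean for
intensities — array probes map many-to-one) with a warning; duplicate
sample IDs are errors. Zero-variance genes get unit scale (their
standardized column is zero, so they can never be selected). Gene matching
across datasets is plain string equality; no identifier translation is
attempted. Barcode bin boundaries at exactly 50/100/1000 CPM go to the
lower-named bin ([0,50), [50,100], (100,1000], (1000,∞)). Hierarchical
clustering uses 1 − Pearson over the chosen gene list, complete linkage,
with scipy's deterministic merge order; a zero-variance sample is an error
naming the sample. The stage-partition rule "high in an organ" is
organ-mean > 10× that gene's mean over all samples of the stage dataset
(per-gene baseline); a whole-matrix-mean variant is available behind a flag
since the sentence defining it is ambiguous.

## Problem sizes

Defaults were chosen so a full run is comfortable on a laptop core: the
benchmark atlas is 2000 genes × 40 samples with a 500-gene pool (~30 s per
cross-validated fit), the acceptance script completes in about two minutes,
and the test suite in about two. All stochastic steps take explicit seeds;
nothing reads the wall clock.
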