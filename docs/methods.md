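# Methods

## Scope and data model

`omicstack` discovers molecular subgroups from four stacked omics layers and
trains classifiers to assign those subgroups to new samples. All matrices
are sample-major. Layers carry a datatype tag with platform-specific
conventions: F1 (mRNA, FPKM-like, non-negative, zero-inflated), F2 (miRNA,
RPKM-like, same), F3 (methylation beta values in [0,1], per-probe chromosome
annotation, missing values), F4 (protein, real-valued, missing values).

## Preprocessing

Filters are strict ("more than"), so a feature exactly at a threshold is
retained:

| step | applies to | default |
| --- | --- | --- |
| zero-fraction filter | F1, F2 | drop if > 0.20 |
| missingness filter | F3, F4 | drop if > 0.10 |
| sex-chromosome filter | F3 | drop chrX/chrY probes |
| top-k SD cut | F1, F3 | k = 2000 (skipped when fewer features exist) |
| KNN imputation | F3, F4 | K = 5 |

The SD ranking uses observed entries only (ddof = 1) because for F3 it runs
before imputation; ties break by original feature order (stable sort).
Imputation replaces each missing cell with the mean of the feature over the
K nearest samples (Euclidean distance over mutually observed features;
backed by scikit-learn's `KNNImputer`, whose nan-distance semantics match
this definition — an exhaustive oracle test pins the behaviour). Layers are
filtered first, then stacked over the intersection of their sample sets with
datatype-prefixed feature IDs; stacking copies values bit-exactly.

Normalization happens at integration time, not during preprocessing:
log2(x+1) for the count-like F1/F2 columns, then per-feature z-scaling of
every column. The z-scaling is what allows a mixed-scale concatenation to
train a single network; it is deliberately **not** applied on the PCA and
no-reduction branches (see below).

## Autoencoder integration

The autoencoder is a symmetric feed-forward network written on numpy:
encoder widths `(h1, ..., bottleneck)`, mirrored decoder, tanh on every
hidden layer (bottleneck included), linear output. Training minimises mean
squared reconstruction error with Adam (β1 = 0.9, β2 = 0.999), minibatches
of 64, on a seeded 90/10 train/validation split of samples. Training stops
at `max_epochs` (default 500) or when the validation loss has not improved
for `patience` = 10 consecutive epochs; the weights of the best-validation
epoch are restored. Across an architecture grid the selected model minimises
|train loss − validation loss| (an overfitting guard), ties broken by lower
validation loss, then fewer parameters.

Defaults for full-scale runs: bottleneck 100, one or two hidden layers from
{2048, 1024, 512}, learning rates {1e-3, 1e-4, 1e-5} (`default_grid`). The
desk-scale runs in the tests and the acceptance script use (64, 16) or
(32, 8) encoders sized to their synthetic inputs.

`pca_reduce` is the linear baseline: **centered** PCA scores keeping the
smallest number of leading components whose cumulative explained variance
reaches `variance_fraction` (default 0.99; 1.0 keeps all components with
nonzero eigenvalue). It does not rescale features. Consequently the
AE-vs-PCA comparison contrasts the full pipelines as practised: a network
that requires (and gets) z-scaled input against a linear projection of the
stacked values. On z-scored input, 99%-variance PCA is nearly lossless and
k-means is rotation-invariant, so the two branches become statistically
indistinguishable on this generator — the contrast would then measure
nothing. This choice is the package's own reading of an underspecified
protocol and is stated here so users can pass `normalize(X)` to
`pca_reduce` themselves if they prefer symmetric scaling.

## Consensus clustering and model selection

For each K in `k_range` (default 2..20), `reps` (default 1000) K-means runs
are executed on random floor(0.8·n) subsamples drawn without replacement
(k-means++ with `n_init` restarts per rep, default 10; seeded stream). The
consensus matrix holds, per sample pair, co-clustered runs / co-sampled
runs (0 when never co-sampled; unit diagonal). With C(K, u) the empirical
CDF of the upper-triangle off-diagonal consensus values, the proportion of
ambiguously clustered pairs is P(K) = C(K, u2) − C(K, u1), i.e. the fraction
of pairs with consensus in (u1, u2]; u1 = 0.1, u2 = 0.9.

PAC alone drifts toward large K, so it is calibrated against `B` (default
25) reference datasets: draws from a single multivariate Gaussian with the
empirical mean and feature covariance of the clustered representation
(eigendecomposition sampling, negative eigenvalues floored at zero) — data
with correlation structure but K = 1 truth. The same B reference datasets
are reused across all K. RCSI(K) = log10(mean_b P_rf(K,b)) − log10(P_rl(K));
any PAC below 1/(number of sample pairs) is floored there to guard the
logarithm. The selected K maximises RCSI, exact ties going to the smaller K.

Final labels come from K-means on the full data, always with ≥ 10 restarts
even when `n_init` is reduced for the subsampled reps — a single
poorly-initialised full-data fit would otherwise corrupt the labels while
leaving the stability scan untouched. `ref_reps` lets desk-scale configs
run fewer consensus reps per reference dataset than on the real data
(defaults to `reps`). Silhouette widths are mean per-sample silhouettes
(Euclidean; singletons contribute 0).

## Characterization

Survival differences across subgroups use the k-group log-rank test
(lifelines; k−1 degrees of freedom) on overall and disease-free survival,
with Kaplan-Meier coordinates returned per cluster. A brute-force
observed-minus-expected implementation in the tests pins the statistic to
1e-8.

Differential features per datatype: one-way ANOVA across clusters per
feature, plus one-vs-rest Welch t-tests per cluster (the "pairwise" tests,
interpreted one-vs-rest so each feature gets a single per-cluster effect;
constant features get p = 1 and are never selected). Benjamini-Hochberg
correction runs within datatype over the ANOVA p-values. Effects are
log2((mean_in + 1)/(mean_rest + 1)) for the ratio-scale F1/F2 and plain mean
differences for the bounded/log-like F3/F4. Selection requires q ≤ 0.01 and
effect magnitude ≥ 5 (two-sided by default; `two_sided_fc=False` gives the
literal one-sided reading). Note the magnitude threshold of 5 is calibrated
to ratio-scale data; F3 mean differences are bounded by 1, so selection
there needs a datatype-appropriate threshold (exposed in the config).

## Classifiers

Splits: 10% test, then 10% of the remainder as validation, stratified by
label; under the holdout protocol the training set splits 60/40 into
L0-train/L1-train (stratified, disjoint). L0 models: radial-kernel SVM with
probability outputs, random forest, and a one-hidden-layer FFNN (hidden
width ≈ (inputs+classes)/2, capped at 256). Hyperparameters are tuned by
stratified 5-fold CV repeated 10 times (mean accuracy) over small standard
grids — SVM C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01}; RF trees ∈ {250,
500}, feature subsets {√p, p/3}; FFNN learning rate ∈ {1e-3, 1e-4, 1e-5}.
Tests and the acceptance script pass lighter grids and 3-fold/1-repeat CV,
since on separable synthetic data the tuning is inert. The classifier MLPs
stop on training-loss convergence rather than a validation early stop:
small networks sit at chance-level validation accuracy for their first ~50
epochs, so a patience-based validation stop aborts before any learning.

Linear fusion scans all 5151 (α, β, γ) triples on the 0.01 grid summing to
1, scoring fused accuracy on a selection set the L0 models never saw — the
validation split (no holdout) or the L1 partition (holdout) — and keeps the
first maximiser in lexicographic order. Nonlinear stackers (logistic
regression; small FFNN) train on the concatenated 3K-dimensional
probability vectors of the L1-train samples. Feature-level fusion simply
concatenates the selected features of two datatypes (F3 plus one other).
Prediction for new samples aligns features by ID, fills up to 10% missing
features with training means, and rejects inputs missing more.

## Synthetic data

The generator draws per-sample latent vectors z = center[cluster] + N(0, I)
in `latent_dim` = 10 dimensions, with cluster centers N(0, `cluster_sep`²)
(default 3.0). Each layer observes tanh(zW + b) through its own random map
(W ~ N(0, 1/√d)) plus Gaussian noise (`layer_noise`, default 0.3), then a
platform link: exp(2 + 1.5·h) for F1/F2 (positive, right-skewed) with
Bernoulli zero-inflation (5% / 10%); a logistic squash into (0,1) for F3;
2·h for F4. F3/F4 get per-feature missingness from a two-rate mixture (2%
for most features, 15% for a 20% / 10% minority — so some features exceed
the 10% drop threshold by construction). A configurable fraction of F3
probes (5%) is annotated chrX/chrY, the rest cycling chr1..chr22. Survival
times are exponential with per-cluster hazards (default (1/1500)·1.6^k per
day) under independent uniform censoring whose window is solved numerically
for the target censoring fraction (default 0.3); DFS uses 1.3× the OS
hazards. Cluster sizes are balanced, guaranteeing ≥ 2 samples per cluster.

What this emulates: shared latent cluster structure across layers,
layer-specific nonlinear maps, platform value ranges, zero inflation,
structured missingness, outcome differences detectable by log-rank. What it
does not: batch effects, tumor purity gradients, count overdispersion,
feature-feature regulatory networks, realistic correlation lengths, or any
real biology. Passing tests therefore demonstrate the pipeline's
correctness and its qualitative behaviour (stability selection, fusion
dominance), not performance claims about real cohorts.

`toy_fixture()` is a fixed 12-sample study with hand-constructed filter
violations (2 F1 high-zero features, 1 F2 high-zero, 1 F3 high-missing, 1
chrX probe, 1 F4 high-missing) used for exact filter accounting.

## Numerical choices and degenerate inputs

- PAC is computed from one integer count so C(u2) − C(u1) is exact.
- RCSI floors PACs at 1/(n choose 2) before logs; `rcsi_score` exposes the
  floor.
- Consensus entries for never-co-sampled pairs are 0 (with 1000 reps at 80%
  subsampling the probability of such a pair is negligible).
- Reference covariance eigenvalues are clipped at 0; an all-constant matrix
  is an error.
- Constant features: z-scaling leaves them at 0; ANOVA returns p = 1.
- Empty post-filter layers, disjoint sample sets, single-class training
  data, all-censored survival, K ≥ n are explicit errors.

## Desk-scale problem sizes

The test suite and acceptance script run the generator at n = 300–1000
samples with 230–400 stacked features, consensus scans with 30–100 reps,
B = 5–20 references at 8–20 reps each, and k-means with 2–3 restarts per
subsample rep (final labels always ≥ 10 restarts). These sizes exercise
every code path while keeping a full run in minutes on one CPU; all
defaults for full-scale analyses remain the protocol values stated above.

## Known limitations

- The autoencoder is plain (no denoising/variational variants) and CPU-only.
- Reference simulation assumes a Gaussian null; heavy-tailed latent spaces
  would need a rank-based alternative.
- Linear-fusion weight search is exhaustive on a fixed 0.01 grid; finer
  grids scale quadratically.
- `SVC(probability=True)` is deprecated in scikit-learn 1.9; a future
  release will switch the SVM probabilities to `CalibratedClassifierCV`.
- With `overlap_frac` < 1 the generator produces partially overlapping
  sample sets; survival tables still cover all samples, and downstream
  stages operate on the stacked intersection.
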