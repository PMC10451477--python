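# Methods

## Problem and scope

The package implements a two-level classification pipeline for bulk
microarray gene-expression matrices with a binary outcome: adenocarcinoma
(Adeno, the majority/positive class) versus mesothelioma (Meso). A study
matrix has 12,533 gene probes × 181 subjects (150/31) with non-negative,
strongly right-skewed intensities. Everything here runs on synthetic
matrices shaped like that cohort; no external data is bundled or fetched.

## Synthetic data generator

Intensities are log-normal: gene g draws a baseline log-intensity
b_g ~ N(μ₀, σ₀²) with μ₀ = 8, σ₀ = 1 (intensities on an arbitrary scanner
scale, median ≈ e⁸ ≈ 3000); each observation adds N(0, σ²) log-scale noise
with σ = 0.5. A designated set of `n_informative_genes` (default 300,
≈2.4% of probes — a plausible differential-expression fraction) has its
log-mean shifted by `effect_size` (default 1.0, i.e. an e-fold change) in
Meso columns. The generator is a pure function of its config including the
seed, and the informative mask is retained so selection-recovery
experiments have ground truth.

What this emulates: the marginal heavy tail (large positive skewness and
kurtosis), the 150/31 imbalance, and a tunable class signal. What it does
not emulate: gene–gene correlation structure, probe-level artifacts, batch
effects, or any real biology of the LH2-style cohorts. Passing tests
therefore demonstrate algorithmic correctness and calibration, not
clinical performance; headline accuracies published for the real cohort
are out of reach by construction and are not asserted anywhere.

The log-normal family was chosen as the simplest non-negative heavy-tailed
model; any such family would serve, and no claim is made that the real
cohort is log-normal.

## Spectral feature extraction

Each subject's profile is treated as a 1-D signal in the array's native
probe order (the ordering is arbitrary but fixed, which is all the method
requires — the transform is a dimensionality reduction, not a claim about
genomic periodicity). Frames of length M = 4096 at hop 2048 are tapered by
a symmetric Blackman window (denominator M−1, so w[0] = w[M−1] = 0) and
transformed with a 4096-point real FFT; the signal is zero-padded so the
last frame is complete (a 12,533-sample profile gives ceil(12533/2048) = 7
frames). One-sided magnitudes are averaged across frames — the simplest
order-invariant frame reduction; max-magnitude is available as an option.
The output is 4096/2 + 1 = 2049 features per subject, which fixes the
transform size: it is the only choice consistent with the published
2049-row reduced matrices.

The per-frame Parseval identity (one-sided energy with conjugate-symmetry
doubling = transform_size × windowed-signal energy) is enforced in the
test suite at 1e−6 relative error, and the transform is checked against an
O(N²) direct-sum DFT oracle at 1e−9 on short signals.

### Statistical battery

Per class: pooled mean/variance/skewness/kurtosis (Pearson kurtosis, i.e.
not excess), mean pairwise Pearson correlation between subject columns,
permutation entropy (order 3, lag 1, natural log, normalized by log 6) and
sample entropy (m = 2, r = 0.2·sd, with the standard N−m template
convention) averaged over subjects, a variance-ratio f-statistic and
Welch t-test against the other class, and the leading canonical
correlation between the two classes' principal subspaces (rank
min(n_subjects)−1 capped at 10, computed from centred SVD bases; an
eigenvalue ridge of 1e−8 is the fallback for pathological input).
Entropy parameters are the literature defaults; the source tables report
these statistics without parameters. Constant input flags a degenerate
summary (skewness/kurtosis 0) rather than raising.

## Wrapper feature selection

Both metaheuristics minimize a wrapper fitness over fixed-size column
subsets. The default fitness trains a softmax discriminant on the subset
(feature-standardized, 100 epochs inside the search) and returns the
training MSE of its outputs mapped to the class targets (0.85/0.65):
observed value = posterior-weighted target, target = true-class target.
Fitness values are memoized per subset, which matters once the swarm
concentrates.

* **PSO** (swarm 30, 100 iterations, ω = 0.72, c₁ = c₂ = 1.49 —
  constriction-style defaults): binary particles, one bit per candidate;
  velocities squash through a logistic into bit probabilities, bits are
  sampled, then repaired to exactly `subset_size` set bits by keeping or
  adding the highest-probability bits (ties to the lowest index).
* **Harmony search** (memory 20, 200 iterations, HMCR = 0.9, PAR = 0.3):
  each slot of a new subset is taken from a random memory member with
  probability HMCR (pitch-adjusted ±1 index with probability PAR), else
  drawn uniformly; duplicates are repaired preferentially from the current
  memory support, and the worst memory entry is replaced on improvement.

Both return the best-ever subset with a non-increasing best-so-far trace,
fully deterministic given the config seed. The published pipeline selects
subject columns per class (30 Adeno / 6 Meso);
`select_subjects_per_class` provides that axis, while the generic
selectors operate on whatever candidate axis the caller passes.

The Friedman statistic is computed from within-block average ranks as
12/(n·k·(k+1))·ΣRᵢ² − 3·n·(k+1) with a χ²(k−1) p-value; it is invariant
to monotone transforms and exactly 0 under complete ties.

## Classifiers

All models order classes [Adeno, Meso] and break ties toward Adeno.

* **Nonlinear regression.** Per sample, y = Σⱼ(T − xⱼ)² with the Adeno
  target as reference point; z = k₁y + k₂²y² + k₃³y³ with k₂ = k₁/10,
  k₃ = k₂/10; threshold g = f + d₀ where f = min training z and d₀ is the
  sum of squared deviations of the training scores from their mean; the
  side of g assigned to Adeno is chosen on the training data. k₁ is
  grid-searched over 200 points on (0,1] minimizing training MSE. Because
  z ≈ k₁y for small k₁ while d₀ scales as k₁², the grid effectively moves
  the threshold across [min y, min y + spread], which is what makes the
  fixed g = f + d₀ rule usable. Expects features on a common [0,1]-like
  scale.
* **GMM.** One K-component full-covariance mixture per class (default
  K = 2), EM with k-means++-style seeding, covariance ridge 1e−6,
  log-likelihood tolerance 1e−6, 1000-iteration cap; a collapsed component
  is reseeded once, then raises. K = 1 reduces to the closed-form MLE.
  Full covariances are intended for post-selection feature counts
  (d ≲ n); on the raw 2049-feature spectra, run selection first — the
  d × d covariances are otherwise ill-conditioned and EM is slow.
* **Softmax discriminant.** Full-batch gradient descent on cross-entropy,
  learning rate 0.5 (halved up to five times on divergence), stop at loss
  change < 1e−8 or 1000 epochs; expects standardized features. An L2
  penalty coefficient is exposed (an interpretation of the published
  γ = 0.5 tuning constant, which has no slot in the update equations);
  the shipped default is 0 so the plain update rule is what runs.
* **Naive Bayes.** Gaussian per-feature likelihoods with class-wise
  variance floored at α × pooled variance, α = 0.06; priors are class
  fractions. The floor makes constant features harmless.
* **SVM.** Simplified-SMO dual solver (pairwise coordinate ascent in the
  [0, C] box, KKT tolerance 1e−3, deterministic seeded partner choice),
  kernels linear / polynomial (γ xᵀz + r)^d / RBF exp(−|x−z|²/2σ²), with
  the published per-kernel defaults (linear C = 0.85; polynomial C = 0.76,
  γ = 10, r = 0, d = 2 — the degree is unstated in the source, 2 is the
  shipped default; RBF C = 1, σ = 100). The kernel Gram matrix is checked
  for positive semi-definiteness up front. σ = 100 suits standardized
  2049-feature vectors (squared distances ≈ 2d); on low-dimensional toys
  pass a width of order the data scale. The solver is cross-checked
  against an independent reference SVM in the tests, never replaced by it.

Class targets: T_Adeno = 0.85, T_Meso = 0.65 with mapping constraints
(each target above its class's mean normalized feature mean). The
published separation requirement |T_Adeno − T_Meso| ≥ 0.5 is violated by
the published values themselves (0.2 < 0.5); the check is evaluated and
reported as a warning, deliberately not enforced or "fixed".

## Evaluation

Stratified 10-fold cross-validation by default (the 150/31 imbalance makes
unstratified folds risk losing Meso entirely); a single stratified 85/15
split is available since the source describes both protocols. Features are
standardized per fold on training statistics. Fold confusion matrices are
summed before computing headline metrics (micro-averaging; the source does
not state its pooling rule). Metrics follow the exact published formulas,
including P_e = [(TP+FP)(TP+FN) + (FP+TN)(FN+TN)]/N² for kappa — this
exact form was verified to reproduce the published kappa values. Zero
denominators return 0 with a degenerate flag. Feature selection, when
enabled, runs once on the full feature matrix before cross-validation,
matching the published two-stage flow; a leakage-free variant would
re-select per training fold at k× the cost.

`reconstruct_confusion` brute-forces TP ∈ [0, n_pos], TN ∈ [0, n_neg]
against printed accuracy/precision/recall; with both class sizes fixed the
minimizer is unique for the tables reproduced in the tests.

## Problem sizes and numerics

The test suite exercises the full 12,533 × 181 shape where the claim is
structural (feature counts, null calibration) and scaled-down matrices
(256 genes, 64-point transforms, 60 subjects) where the claim is
algorithmic, keeping the default suite under a minute. Planted-subset
recovery uses 10 candidates with 3 signal columns (log shift 1.5,
120 samples): large enough that the wrapper fitness's training-error
optimum is the planted triple — with fewer samples a flexible learner can
overfit a noise column past the third signal column, which is a property
of wrapper selection on training error, not a bug. Random-number use is
routed through seeded `numpy.random.default_rng` everywhere; reports are
byte-identical across reruns of the same config.

## Known limitations

* The generator's independence across genes makes selection and
  classification easier than on real arrays with correlated probes.
* Pre-CV feature selection (above) mildly optimistic-biases CV estimates.
* GMM with full covariance and the NLR grid are intended for
  post-selection dimensionality.
* No probability calibration, multi-class support, ROC/AUC, or wavelet
  transforms; the convolutional branch of the original study is out of
  scope, though its published metric rows are used as reconstruction
  examples because the metric suite is architecture-independent.
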