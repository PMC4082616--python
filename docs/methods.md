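# Methods

This note documents the models, numerical conventions, and design choices
behind `sparsekm`, and what the synthetic-data experiments do and do not
demonstrate.

## The clustering model

Sparse k-means maximizes the weighted between-cluster sum of squares
`Σ_j w_j·BCSS_j(C)` over partitions C and feature weights w subject to
`‖w‖₂ ≤ 1`, `‖w‖₁ ≤ s`, `w ≥ 0`, with squared Euclidean distance
throughout. The two sub-problems have exact solutions and are alternated:

- **Partition step.** k-means (Lloyd) on the matrix whose feature j is
  scaled by `√w_j`. Initial centroids are k distinct sample rows drawn at
  random; subsequent alternations warm-start from the current partition's
  centroids. Nearest-centroid ties break toward the lowest cluster index.
  An emptied cluster is re-seeded at the point farthest from its assigned
  centroid.
- **Weight step.** With the partition fixed, the optimum is
  `w ∝ (BCSS − Δ)₊` renormalized to unit L2 norm, with soft threshold
  Δ = 0 if the L1 constraint is already slack, otherwise found by bisection
  until `‖w‖₁ = s` within 1e-8. Weights are invariant to the scale of the
  BCSS vector, which is exploited for numerical safety (the vector is
  divided by its maximum first). Exact ties at the maximal BCSS can make
  `‖w‖₁ = s` unreachable by thresholding (a tied block renormalizes to
  L1 = √m regardless of Δ); the deterministic tie-break keeps the first
  ⌊s²⌋ tied coordinates with equal weight.

The alternation stops when the relative L1 change of the weights falls
below `weight_tol = 1e-4` or after `max_iter = 20` rounds. The whole
alternation is restarted `n_starts = 20` times (default) from independent
random initializations and the best final objective is kept. This
best-of-restarts convention is what makes the optimizer reliably attain the
global optimum on small instances (verified against exhaustive enumeration
of all 2-partitions with analytically optimal weights in the test suite); a
single run with a multi-start first k-means only — the convention of some
reference implementations — reached the global optimum on barely a third of
tiny test instances.

Cluster labels are renumbered 1..k by order of first occurrence, so outputs
are comparable across runs.

## Model selection and inference

For each k in 2–5 (default) and each of 50 tuning values s spaced linearly
over (1.2, √p], the gap statistic is

    gap(k, s) = log O(X; k, s) − mean_b log O(X*_b; k, s),

difference of logarithms, with O the maximized weighted BCSS and X*_b
(b = 1..25 by default) obtained by permuting samples independently within
each feature. One set of permuted matrices is generated per search and
reused across the whole grid (common random numbers); every (k,
permutation) fit draws from an independent seed stream. `sd` is the sample
SD (ddof = 1) of the null log-objectives, with no √(1+1/B) inflation — this
matches the CI arithmetic used in the field's reports (a gap of
1.834 ± 0.014 gives the 95% CI 1.807–1.861). The selected (k, s) maximizes
the gap, ties broken toward smaller k then smaller s. Inference assumes
gap/sd is standard normal: one-sided upper-tail p, CI = gap ± 1.96·sd. When
sd = 0 the inference is flagged degenerate and p reported as exactly 0 or 1.

A null fit on a permuted matrix can in principle have zero objective
(log undefined); such permutations are redrawn and the event logged.

## The integrative extension

Given D feature-standardized sources sharing the sample order:

1. Each source is multiplied by `√(T/TSS_d)` where T is the first source's
   total sum of squares, so no source dominates by size alone. TSS is
   partition-independent, so the scaling is applied once up front.
2. One shared partition is fitted by k-means on the horizontal
   concatenation of the `√w_d`-scaled sources, while each source's weight
   vector is updated separately from its own per-feature BCSS under its own
   bound `s_d = 1 + t(√p_d − 1)` with a single tuning parameter
   `t ∈ (0, 1]`. At t = 1 every `s_d = √p_d` and no sparsity is enforced
   anywhere; the joint objective is `Σ_d Σ_j w_dj·BCSS_dj`.
3. The gap-statistic null permutes whole sample rows independently within
   each source (identity permutation excluded when n ≤ 5). Because each
   source's internal geometry is preserved exactly, the null objective
   retains all single-source structure and the gap isolates *cross-source*
   (joint) structure. The (k, t) grid search mirrors the single-source one,
   with t spaced over (0, 1].

Per-source weight vectors each under their own L2/L1 constraints (rather
than one global weight vector) is a deliberate design choice: it is what
makes per-source sparsity levels reportable and comparable, and what the
`s_d` mapping presupposes. With a single source, the integrative fit at
tuning t is identical (same seed stream) to the single-source fit at
`s = 1 + t(√p − 1)` — they share one optimizer.

## Preprocessing conventions

- **Quantile normalization** equalizes each sample's value distribution to
  the cross-sample mean order statistics; ties receive the mean of the tied
  quantiles (the `ties='mean'` convention). The operation is idempotent;
  its "all samples share one multiset" defining property is exact only for
  tie-free data.
- **CV filter**: coefficient of variation SD/mean per feature, computed on
  the log2 quantile-normalized scale (pipeline order is fixed:
  normalization first). Features strictly above the given percentile
  (default 75) of the CV distribution are kept; percentile 0 disables the
  filter entirely rather than dropping the minimum-CV feature.
- **Covariate adjustment**: per-feature OLS on an intercept + dummy-coded
  categorical + continuous covariates; internally studentized residuals
  `r_i/(s√(1−h_ii))` are passed on. Raw residuals are exactly orthogonal to
  the design; the leverage rescaling perturbs that orthogonality by a small
  amount (≈0.003 SD units in simulation), which is why downstream checks
  use a loose tolerance. Features fit perfectly by covariates (zero
  residual variance) are dropped with a log record; rank-deficient designs
  are rejected naming the collinear covariates.
- **Standardization** is feature-wise (each feature mean 0, SD 1), the
  convention the sparse-clustering objective assumes; sample SD (n−1)
  everywhere. Constant features are dropped with a warning.
- **Missing data**: traits with any missing value are removed before
  clustering (e.g. a 26-trait table with 2 gapped traits enters the
  analysis with 24); clinical association tests use pairwise deletion with
  per-variable missingness logged.

## The synthetic cohort generator

The generator emulates the kind of study this package targets: n = 44
patients by default, two BeadChip-like expression sources of 11 804 probes
(blood-like and dura-like) and a 24-trait morphometric source. Its model:

- latent log2 expression = feature baseline ~ N(8, 2) + class offset +
  covariate effects + N(0, 1) noise, returned as 2^x raw intensities so the
  preprocessing stack is exercised; trait sources use baseline ~ N(0, 2)
  and stay on their continuous scale;
- a planted partition of k_true classes drawn near-balanced (equal-
  probability multinomial, redrawn until all classes are occupied), either
  shared across sources (joint structure) or drawn independently per
  source;
- each informative feature (a random subset of the configured fraction)
  gives each class an offset of 0 or δ (never constant across classes), so
  some pair of classes differs by δ within-class SDs on that feature;
- covariates: age at surgery uniform on 1–18 years (pediatric cohort), age
  at MRI slightly earlier, sex/race at the approximate frequencies of the
  motivating cohort, two surgeons, RIN uniform on 6–10 (samples below RIN 6
  would fail QC and are not generated). Effects are additive on the log2
  scale with per-feature coefficients ~ N(0, magnitude²) applied to
  standardized covariates; the RIN effect applies to dura-like sources
  only;
- a questionnaire-style clinical table (binary + continuous variables, a
  configurable subset associated with the planted partition) with entries
  missing independently at rate 0.18 by default (≈ the fraction of
  non-responders in the motivating study), missingness independent of
  class.

Seeding is hierarchical (one stream per source plus streams for
covariates, partition and clinical table), so adding a source leaves
earlier sources bit-identical.

What the generator does *not* emulate: probe-level bead replicates, array
control probes, batch effects beyond the modeled covariates,
heavy-tailed/correlated noise, or class structure expressed through
variances rather than means. Passing tests therefore demonstrate that the
algorithms behave as specified under a mean-shift Gaussian model with
additive covariate nuisance — not that any particular real dataset contains
recoverable subtypes.

## Simulation conditions used by the acceptance checks

All experiment sizes were chosen to be realistic for the target study scale
while keeping a full run in minutes on one CPU; sparsity-free steps use the
study-scale defaults above, clustering property checks use trait-type
sources without covariate effects so the property under test is isolated.

- *Reduction (s = √p)*: n = 60, p = 200, δ = 2, 20% informative, 20
  replicates. A clearly separated two-class structure is used deliberately:
  the reduction to standard k-means is an algebraic/algorithmic property,
  and testing it requires an unambiguous k-means optimum — at weak signal
  both algorithms latch onto noise and their partitions differ for reasons
  unrelated to the property.
- *Recovery*: n = 60, p = 500, δ = 1.5, 10% informative, k = 2, fit at
  s = √50 (the L1 bound matched to the planted informative count), 20
  replicates.
- *Model selection*: n = 60, p = 50, δ = 2, 20% informative, k_true = 3,
  grid k = 2–5 × 10 tuning values, 10 permutations, 10 restarts, 20
  replicates. p = 50 with a fifth of features informative represents a
  moderate-dimensional source (the regime where k-selection is
  well-posed); the restart count is halved from the default to keep the
  ~9 000 grid fits fast.
- *Null calibration*: pure N(0,1) noise, n = 40, p = 50, k = 2, s = √p,
  25 permutations, 20 replicates.
- *Joint-structure specificity*: two sources, n = 50, p = 100 each, δ = 2,
  10% informative, fitted at (k = 2, t = 0.5) with 25 permutations;
  20 replicates with shared and 20 with independent planted partitions.
- *Oracles*: Rand/adjusted-Rand against brute-force pair counting
  (exhaustive over all partition pairs for n ≤ 5, seeded samples for
  n = 6–8); the clustering objective against exhaustive enumeration of all
  2-partitions with analytically optimal weights on n ≤ 8, p ≤ 3 instances
  (local optima are possible in an alternating scheme; the check requires
  ≥ 95% exact matches).

## Numerical and degenerate-case conventions

- Bisection tolerance for the weight update: `|‖w‖₁ − s| ≤ 1e-8` (≤ 200
  iterations). Equal-TSS scaling is exact to 1e-8 relative.
- BCSS entries are clipped at 0 (they are non-negative analytically;
  floating-point cancellation can produce −1e-16).
- All-zero BCSS (e.g. a null fit with no structure at all) yields uniform
  weights with a degenerate-solution warning.
- k greater than the number of distinct sample rows is rejected.
- Logistic characterization flags perfect separation (non-convergence or
  |coefficient| > 15) and reports p as NA rather than a misleading number.
- Fisher's exact test enumerates 2×C tables under the point-probability
  two-sided rule up to 10⁶ tables, then falls back to a Monte-Carlo exact
  test (20 000 multivariate-hypergeometric draws) with a reported standard
  error; R×C tables with R > 2 always use the Monte-Carlo route.
- The t-test variance pre-test is a two-sided F ratio test at α = 0.05,
  choosing pooled vs Welch.

## Known limitations

- The gap statistic's normality assumption is an approximation; with 25
  permutations the SD itself is noisy, and the printed p-values should be
  read as orders of magnitude, not exact tail probabilities.
- The alternating optimizer offers no global-optimality guarantee; the
  enumeration checks bound its behavior only on tiny instances.
- The logistic trait-association at n ≈ 40 has slope SE ≈ 0.45; odds-ratio
  estimates at that size are directional evidence, not precise effect
  sizes.
- Partially overlapping sample sets across sources are not supported in the
  integrative fit (samples must be present in all sources); concordance
  comparisons do intersect on sample ids.
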