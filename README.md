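# sparsekm

Sparse and integrative sparse k-means clustering for unsupervised
disease-subtype discovery from heterogeneous patient-level data — e.g. bulk
expression profiles from two tissues plus a table of MRI-derived
morphometric traits for the same cohort. The package provides the full
analysis stack: microarray-style preprocessing, feature-weighted clustering
of each data source, a multi-source extension that looks for one patient
partition supported jointly by all sources, permutation-based model
selection and significance, and downstream class characterization. A
synthetic-cohort generator with planted ground truth makes every stage
testable end to end.

It is written for analysts running subtype-discovery studies on modest
cohorts (tens of patients, thousands of features), where feature selection
and honest significance assessment matter more than scale.

## The method

**Sparse k-means.** Standard k-means minimizes the within-cluster sum of
squares over all p features, which in expression data lets thousands of
uninformative probes drown the signal. Sparse k-means instead maximizes a
*weighted* between-cluster sum of squares (BCSS) with a lasso-type
constraint on the feature weights:

    max_{C, w}   Σ_j  w_j · BCSS_j(C)
    subject to   ‖w‖₂ ≤ 1,   ‖w‖₁ ≤ s,   w_j ≥ 0

where `BCSS_j = TSS_j − WSS_j` is feature j's between-cluster sum of
squares under partition C. The tuning parameter `s ∈ (1, √p]` controls
sparsity: at `s = √p` nothing is thresholded out and the partition
coincides with standard k-means; as `s → 1` the weight vector concentrates
on the few features that discriminate the classes. The optimizer alternates
k-means on the `√w_j`-scaled data with a closed-form weight update
(soft-thresholded BCSS, renormalized), restarted from multiple random
initializations, keeping the best objective.

**Model selection and inference.** The number of classes k and the bound s
are chosen by maximizing the gap statistic over a (k, s) grid:

    gap(k, s) = log O(X) − mean_b log O(X*_b)

where O is the maximized objective and X*_b are null matrices obtained by
permuting samples independently within each feature. Treating the gap as
approximately normal with the permutation SD gives a z-score, an upper-tail
p-value and a 95% CI (gap ± 1.96·sd).

**Integrative extension.** For several sources sharing the same samples,
one partition is fitted jointly while each source d keeps its own weight
vector and its own sparsity bound `s_d = 1 + t(√p_d − 1)`, `t ∈ (0, 1]`, so
the enforced sparsity is comparable across sources of very different sizes.
Sources are first rescaled to equal total sums of squares so the largest
one cannot dominate. Crucially, the gap null here permutes *whole sample
rows within each source*: each source's internal structure is preserved and
only the cross-source alignment is destroyed, so a significant integrative
gap is evidence of *joint* structure, not of structure in any single
source.

**Preprocessing.** Expression matrices are log2-transformed and quantile
normalized, filtered by coefficient of variation (default: keep the top 25%
most variable features), adjusted for nuisance covariates (age, sex, race,
surgeon; RNA quality for dura-like sources) by per-feature internally
studentized OLS residuals, and feature-standardized (mean 0, SD 1). Trait
tables skip the intensity steps, drop incomplete traits, and go through the
same residualization and standardization.

**Characterization.** Partitions from different analyses are compared by
Rand and adjusted Rand indices; classes are related to clinical variables
with exact count tests (Fisher), t-tests/ANOVA, and covariate-adjusted
logistic regression of class on each morphometric trait.

## Worked example

Simulate a 40-patient cohort with a blood-like expression source (300
probes, 20% carrying a planted 2-class signal of 2 within-class SDs) and a
24-trait morphometric source, preprocess both, and run the integrative
analysis:

```python
import sparsekm as sk

spec = sk.CohortSpec(
    n_samples=40,
    sources=[sk.SourceSpec("blood", 300, informative_fraction=0.2),
             sk.SourceSpec("cranial", 24, "trait", informative_fraction=0.4)],
    k_true=2, effect_size=2.0, seed=7,
)
bundles, truth = sk.generate_cohort(spec)
meta = truth.covariate_table
blood = sk.preprocess_expression(bundles[0], meta,
                                 ["age_at_surgery", "sex", "race", "surgeon"])
cranial = sk.preprocess_traits(bundles[1], meta, ["age_at_mri", "sex", "race"])

search = sk.IntegrativeSparseKMeans([blood, cranial]).select(
    k_range=(2, 3), n_tuning=10, n_permutations=15, n_starts=10, seed=7)
print(search.results.summary())
```

which prints:

```
Integrative sparse k-means clustering: blood-cranial
  k classes                2
  class sizes              1: 15, 2: 25
  tuning parameter t       0.4
  blood: non-zero weights 22 (29.3%), max-weight feature blood_probe46 (0.41), s_d = 4.064
  cranial: non-zero weights 10 (41.7%), max-weight feature cranial_trait9 (0.57), s_d = 2.56
  joint objective          247.9634
  gap statistic            0.323 ± 0.025
  95% CI                   0.274-0.371
  p-value                  2.61e-39
```

Reading the output: the grid search selected two classes at tuning t = 0.4,
which kept 22 of 300 expression probes (29.3% of the 75 surviving the CV
filter) and 10 of 24 traits with non-zero weight; the highest-weight
features are the ones driving the split. The gap statistic of 0.323 with
permutation SD 0.025 means the observed joint objective exceeds the
within-source-permuted null by far more than chance (the CI excludes 0), so
the two sources share a common patient partition — here the planted one:
the fitted labels agree with the ground truth at adjusted Rand 0.90.

The same pipeline is scriptable from the shell
(`sparsekm simulate | preprocess | cluster | select | integrate |
characterize | run`), e.g.:

```
sparsekm simulate --n-samples 40 --k-true 2 --delta 2.0 \
    --sources "blood:300:log2-intensity,cranial:24:trait" --seed 7 --out-dir cohort
sparsekm preprocess --matrix cohort/raw_blood.tsv --metadata cohort/covariates.tsv \
    --kind expression --covariates age_at_surgery,sex,race,surgeon --out blood.tsv
sparsekm select --matrix blood.tsv --k-range 2,4 --n-tuning 8 \
    --permutations 15 --starts 10 --seed 7 --out-prefix blood
```

`sparsekm run --config config.yaml` executes a whole study (every source
individually plus every configured integration) and writes a consolidated
report with per-analysis blocks (optimal k, class sizes, tuning parameter,
non-zero weight counts and percentages, max-weight feature, gap ± sd, CI,
p-value) and a pairwise concordance matrix.

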