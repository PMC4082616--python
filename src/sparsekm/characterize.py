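"""Post-clustering characterization.

Partition concordance (Rand / adjusted Rand), weighted-PCA visualization
coordinates, and class-trait association tests: exact count tests for
categorical variables, t-test/ANOVA for continuous ones, and covariate-
adjusted logistic regression for morphometric traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, rand_score

import statsmodels.api as sm

__all__ = [
    "PartitionConcordance",
    "AssociationResult",
    "compare_partitions",
    "weighted_pca",
    "fisher_exact_2xc",
    "categorical_class_association",
    "continuous_class_association",
    "trait_class_logistic",
]

logger = logging.getLogger(__name__)


@dataclass
class PartitionConcordance:
    """Pair-counting agreement between two sample partitions."""

    rand: float
    adjusted_rand: float
    n_common_samples: int


@dataclass
class AssociationResult:
    """One class-variable association test."""

    variable: str
    test: str
    statistic: float
    p_value: float
    effect: float | None = None  # odds ratio or location difference
    flags: dict = field(default_factory=dict)


def _align(labels_a, labels_b):
    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        common = labels_a.index.intersection(labels_b.index)
        return labels_a.loc[common].to_numpy(), labels_b.loc[common].to_numpy()
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length and carry no sample ids")
    return a, b


def compare_partitions(labels_a, labels_b) -> PartitionConcordance:
    """Rand and adjusted Rand index between two partitions.

    Series inputs are intersected on their sample ids (the common-sample
    count is recorded); array inputs must already be aligned.
    """
    a, b = _align(labels_a, labels_b)
    if len(a) < 2:
        raise ValueError("need at least 2 common samples to compare partitions")
    return PartitionConcordance(
        rand=float(rand_score(a, b)),
        adjusted_rand=float(adjusted_rand_score(a, b)),
        n_common_samples=len(a),
    )


def weighted_pca(matrix, weights, n_components: int = 2):
    """PCA of the matrix with feature j multiplied by its clustering weight.

    Returns (sample scores, proportion of variance explained).  Scores of
    samples from well-separated classes spread along the leading components
    when the weights concentrate on class-discriminating features.
    """
    frame = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(
        np.asarray(matrix, dtype=float)
    )
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != frame.shape[1]:
        raise ValueError("weights must conform to features")
    if not (w > 0).any():
        raise ValueError("all-zero weight vector")
    n_components = int(n_components)
    if n_components > min(frame.shape[0] - 1, frame.shape[1]):
        raise ValueError("n_components exceeds min(n-1, p)")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(frame.to_numpy(dtype=float) * w)
    scores = pd.DataFrame(
        scores,
        index=frame.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, pca.explained_variance_ratio_.copy()


def _log_table_prob(table: np.ndarray) -> float:
    """log P(table | margins) under the multivariate hypergeometric null."""
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    ntot = int(table.sum())

    def lchoose(n, k):
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    # 2 x C: product over columns of C(n_c, a_c), divided by C(N, R1)
    return sum(lchoose(col[c], table[0, c]) for c in range(len(col))) - lchoose(
        ntot, row[0]
    )


def fisher_exact_2xc(table, max_tables: int = 10**6, seed=None):
    """Exact two-sided p for a 2 x C contingency table, point-probability rule.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table.  When
    the enumeration budget is exceeded, falls back to a Monte-Carlo exact
    test (tables drawn from the multivariate hypergeometric) and reports
    the standard error of the estimate.

    Returns (p_value, flags).
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    if (obs.sum(axis=0) < 1).any() or (obs.sum(axis=1) < 1).any():
        raise ValueError("all margins must be >= 1")
    col = obs.sum(axis=0)
    r1 = int(obs.sum(axis=1)[0])
    log_p_obs = _log_table_prob(obs)
    n_tables = int(np.prod([min(c, r1) + 1 for c in col]))
    tol = 1e-9
    if n_tables <= max_tables:
        total = 0.0
        ncols = len(col)

        def recurse(c: int, remaining: int, log_p: float):
            nonlocal total
            if c == ncols - 1:
                a = remaining
                if 0 <= a <= col[c]:
                    lp = log_p + _col_term(col[c], a)
                    if lp <= log_p_obs + tol:
                        total += np.exp(lp)
                return
            tail_cap = int(col[c + 1:].sum())
            lo = max(0, remaining - tail_cap)
            hi = min(col[c], remaining)
            for a in range(lo, hi + 1):
                recurse(c + 1, remaining - a, log_p + _col_term(col[c], a))

        def _col_term(n, a):
            return lgamma(n + 1) - lgamma(a + 1) - lgamma(n - a + 1)

        denom = lgamma(obs.sum() + 1) - lgamma(r1 + 1) - lgamma(obs.sum() - r1 + 1)
        log_p_obs_full = log_p_obs  # already includes denominator
        # recurse accumulates column terms only; shift both sides by denom
        log_p_obs = log_p_obs_full + denom
        recurse(0, r1, 0.0)
        p = total * np.exp(-denom)
        return min(1.0, float(p)), {"method": "enumeration", "n_tables": n_tables}
    rng = np.random.default_rng(seed)
    draws = 20000
    a_rows = rng.multivariate_hypergeometric(col, r1, size=draws)
    log_ps = np.array([
        sum(
            lgamma(col[c] + 1) - lgamma(a + 1) - lgamma(col[c] - a + 1)
            for c, a in enumerate(row)
        )
        for row in a_rows
    ])
    denom = lgamma(obs.sum() + 1) - lgamma(r1 + 1) - lgamma(obs.sum() - r1 + 1)
    hits = (log_ps - denom) <= log_p_obs + tol
    p = (1 + hits.sum()) / (draws + 1)
    se = float(np.sqrt(p * (1 - p) / draws))
    return float(p), {"method": "monte-carlo", "n_draws": draws, "se": se}


def categorical_class_association(
    class_labels, variable, name: str = "variable", seed=None
) -> AssociationResult:
    """Fisher's exact test of class membership x categorical variable.

    Missing values are excluded pairwise (count logged).  Two-class
    partitions use the exact 2 x C enumeration; larger tables use the
    Monte-Carlo exact test under the same point-probability rule.
    """
    cls = pd.Series(np.asarray(class_labels))
    var = pd.Series(np.asarray(variable, dtype=object))
    keep = cls.notna() & var.notna()
    n_missing = int((~keep).sum())
    if n_missing:
        logger.info("%s: excluded %d sample(s) with missing values", name, n_missing)
    table = pd.crosstab(cls[keep], var[keep]).to_numpy()
    if table.shape[0] == 2:
        p, flags = fisher_exact_2xc(table, seed=seed)
    else:
        # transpose trick only valid for 2 columns; otherwise Monte Carlo on rows
        if table.shape[1] == 2:
            p, flags = fisher_exact_2xc(table.T, seed=seed)
        else:
            p, flags = _fisher_mc_rxc(table, seed=seed)
    flags["n_missing"] = n_missing
    return AssociationResult(
        variable=name,
        test="fisher_exact",
        statistic=float(table[0, 0]),
        p_value=p,
        flags=flags,
    )


def _fisher_mc_rxc(table: np.ndarray, seed=None, draws: int = 20000):
    """Monte-Carlo exact test for R x C tables (point-probability rule)."""
    rng = np.random.default_rng(seed)
    row = table.sum(axis=1)
    col = table.sum(axis=0)

    def log_prob(t):
        lp = -sum(lgamma(x + 1) for x in t.ravel())
        lp += sum(lgamma(r + 1) for r in row) + sum(lgamma(c + 1) for c in col)
        lp -= lgamma(table.sum() + 1)
        return lp

    lp_obs = log_prob(table)
    hits = 0
    for _ in range(draws):
        t = np.zeros_like(table)
        remaining = col.copy()
        for i in range(len(row) - 1):
            t[i] = rng.multivariate_hypergeometric(remaining, int(row[i]))
            remaining = remaining - t[i]
        t[-1] = remaining
        if log_prob(t) <= lp_obs + 1e-9:
            hits += 1
    p = (1 + hits) / (draws + 1)
    return float(p), {"method": "monte-carlo-rxc", "n_draws": draws,
                      "se": float(np.sqrt(p * (1 - p) / draws))}


def continuous_class_association(
    class_labels, values, name: str = "variable"
) -> AssociationResult:
    """t-test (2 classes; pooled vs Welch chosen by an F pre-test at
    alpha = 0.05) or one-way ANOVA (> 2 classes) of a continuous variable."""
    cls = pd.Series(np.asarray(class_labels))
    val = pd.Series(np.asarray(values, dtype=float))
    keep = cls.notna() & val.notna()
    groups = [val[keep][cls[keep] == c].to_numpy() for c in sorted(cls[keep].unique())]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 non-missing values per class")
    if all(np.var(g, ddof=1) == 0 for g in groups):
        return AssociationResult(name, "degenerate", np.nan, np.nan,
                                 flags={"zero_within_class_variance": True})
    if len(groups) == 2:
        v1, v2 = (np.var(g, ddof=1) for g in groups)
        f = v1 / v2 if v2 > 0 else np.inf
        d1, d2 = len(groups[0]) - 1, len(groups[1]) - 1
        p_var = 2 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
        equal_var = p_var >= 0.05
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        return AssociationResult(
            name,
            "t_equal_var" if equal_var else "t_welch",
            float(t),
            float(p),
            effect=float(np.mean(groups[1]) - np.mean(groups[0])),
            flags={"variance_pretest_p": float(p_var)},
        )
    f, p = stats.f_oneway(*groups)
    return AssociationResult(name, "anova", float(f), float(p))


def trait_class_logistic(
    class_labels, trait, covariates: pd.DataFrame, name: str = "trait"
) -> AssociationResult:
    """Covariate-adjusted logistic regression of class on a trait.

    Fits class ~ trait + covariates (e.g. age at MRI, sex, race) and
    reports the trait's likelihood-ratio p-value and per-unit odds ratio.
    Perfect separation is flagged and the p-value reported as NA.
    """
    cls = pd.Series(np.asarray(class_labels))
    uniq = sorted(cls.dropna().unique())
    if len(uniq) != 2:
        raise ValueError("logistic characterization requires exactly 2 classes")
    y = (cls == uniq[1]).astype(float).to_numpy()
    tr = np.asarray(trait, dtype=float)
    cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
    if cov.isna().any(axis=None) or np.isnan(tr).any():
        raise ValueError("complete covariates and trait values required")
    x_full = sm.add_constant(
        np.column_stack([tr, cov.to_numpy(dtype=float)]), has_constant="add"
    )
    x_red = sm.add_constant(cov.to_numpy(dtype=float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            full = sm.Logit(y, x_full).fit(disp=0, maxiter=200)
            red = sm.Logit(y, x_red).fit(disp=0, maxiter=200)
        beta = float(full.params[1])
        separated = (not full.mle_retvals.get("converged", False)) or abs(beta) > 15
    except Exception:  # statsmodels raises on perfect separation
        separated = True
        beta = np.nan
    if separated:
        return AssociationResult(
            name, "logistic_lr", np.nan, np.nan,
            flags={"perfect_separation": True},
        )
    lr = 2.0 * (full.llf - red.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return AssociationResult(
        name, "logistic_lr", float(lr), p, effect=float(np.exp(beta))
    )
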