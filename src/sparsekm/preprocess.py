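"""Preprocessing: log2 + quantile normalization, CV filtering, covariate
residualization and feature standardization.

The clustering stages consume matrices in which every feature has been
(1) put on a common within-sample distribution (expression only),
(2) filtered for variability, (3) adjusted for nuisance covariates by taking
internally studentized residuals of a per-feature OLS fit, and
(4) standardized to mean 0 / SD 1.  Sample SD (n-1 denominator) is used
throughout for consistency with the downstream variance decompositions.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bundles import DatasetBundle

__all__ = [
    "log2_quantile_normalize",
    "cv_filter",
    "build_design",
    "studentized_residualize",
    "standardize_features",
    "drop_incomplete_features",
    "preprocess_expression",
    "preprocess_traits",
]

logger = logging.getLogger(__name__)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return pd.DataFrame(np.asarray(matrix, dtype=float))


def log2_quantile_normalize(raw) -> pd.DataFrame:
    """Log2-transform raw intensities, then quantile-normalize across samples.

    After normalization every sample (row) carries the same multiset of
    values: the cross-sample means of the order statistics.  Within-sample
    rank order is preserved; ties map to the mean of the tied quantiles.

    Parameters
    ----------
    raw : array-like or DataFrame, samples x features
        Strictly positive raw-scale intensities.
    """
    frame = _as_frame(raw)
    x = frame.to_numpy(dtype=float)
    if np.any(~(x > 0)):
        i, j = np.argwhere(~(x > 0))[0]
        raise ValueError(
            "non-positive intensity at sample "
            f"{frame.index[i]!r}, feature {frame.columns[j]!r}: {x[i, j]!r}"
        )
    logx = np.log2(x)
    n, p = logx.shape
    ref = np.sort(logx, axis=1).mean(axis=0)  # mean order statistics, length p
    out = np.empty_like(logx)
    grid = np.arange(1, p + 1, dtype=float)
    for i in range(n):
        ranks = rankdata(logx[i], method="average")
        out[i] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def cv_filter(matrix, percentile: float = 75.0):
    """Drop the least-variable features by coefficient of variation.

    CV = SD/mean per feature, computed on the (log2, normalized) input scale.
    Features with CV strictly above the given percentile of the CV
    distribution are retained (default keeps the top 25%).  ``percentile=0``
    disables the filter and retains everything.

    Returns
    -------
    (filtered matrix, kept feature ids)
    """
    if not (0 <= percentile < 100):
        raise ValueError(f"percentile must lie in [0, 100), got {percentile}")
    frame = _as_frame(matrix)
    if frame.shape[0] < 2:
        raise ValueError("cv_filter requires at least 2 samples")
    mean = frame.mean(axis=0)
    if np.any(np.isclose(mean.to_numpy(), 0.0)):
        raise ValueError("cv_filter requires nonzero feature means")
    cv = frame.std(axis=0, ddof=1) / mean
    if percentile == 0:
        return frame, frame.columns
    cut = np.percentile(cv.to_numpy(), percentile)
    keep = cv.index[cv.to_numpy() > cut]
    if len(keep) == 0:
        warnings.warn(
            "degenerate CV filter: no feature strictly exceeds the "
            f"{percentile} percentile (all CVs tied?)",
            UserWarning,
            stacklevel=2,
        )
    return frame[keep], keep


def build_design(metadata: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Intercept + dummy-coded categorical and raw continuous covariates."""
    missing = [c for c in covariates if c not in metadata.columns]
    if missing:
        raise ValueError(f"covariates absent from metadata: {missing}")
    cols = {"const": np.ones(len(metadata))}
    for c in covariates:
        col = metadata[c]
        if col.isna().any():
            raise ValueError(f"covariate {c!r} has missing values")
        if col.nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy()
        else:
            cols[c] = col.to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=metadata.index)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design; collinear columns among {covariates}"
        )
    return design


def studentized_residualize(matrix, metadata: pd.DataFrame, covariates: list[str]):
    """Per-feature OLS on covariates; return internally studentized residuals.

    Each feature y is regressed on the covariate design D; the returned value
    is r_i / (s * sqrt(1 - h_ii)) with r the raw residual, s the residual SD
    and h_ii the leverage.  Features with (numerically) zero residual
    variance are dropped with a log record.
    """
    frame = _as_frame(matrix)
    design = build_design(metadata.loc[frame.index], covariates)
    d = design.to_numpy(dtype=float)
    n, q = d.shape
    if n <= q + 1:
        raise ValueError(f"need n_samples > n_parameters + 1 ({n} <= {q + 1})")
    qmat, _ = np.linalg.qr(d)
    h = np.einsum("ij,ij->i", qmat, qmat)  # leverage = diag of hat matrix
    y = frame.to_numpy(dtype=float)
    resid = y - qmat @ (qmat.T @ y)
    rss = np.einsum("ij,ij->j", resid, resid)
    scale = np.maximum(np.einsum("ij,ij->j", y, y), 1.0)
    degenerate = rss <= 1e-12 * scale
    if degenerate.any():
        dropped = list(frame.columns[degenerate])
        logger.warning(
            "dropping %d feature(s) with zero residual variance "
            "(perfect covariate fit): %s",
            len(dropped),
            dropped[:10],
        )
        resid = resid[:, ~degenerate]
        rss = rss[~degenerate]
        frame = frame.loc[:, ~degenerate]
    s = np.sqrt(rss / (n - q))
    stud = resid / (s[None, :] * np.sqrt(1.0 - h)[:, None])
    return pd.DataFrame(stud, index=frame.index, columns=frame.columns)


def standardize_features(matrix) -> pd.DataFrame:
    """Center each feature to mean 0 and scale to sample SD 1.

    Constant features cannot be scaled and are dropped with a warning.
    """
    frame = _as_frame(matrix)
    sd = frame.std(axis=0, ddof=1)
    constant = sd.to_numpy() <= 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant feature(s) before "
            "standardization",
            UserWarning,
            stacklevel=2,
        )
        frame = frame.loc[:, ~constant]
        sd = sd[~constant]
    return (frame - frame.mean(axis=0)) / sd


def drop_incomplete_features(matrix) -> pd.DataFrame:
    """Remove every feature containing at least one missing value."""
    frame = _as_frame(matrix)
    bad = frame.isna().any(axis=0)
    if bad.all():
        raise ValueError("all features contain missing values; nothing left")
    if bad.any():
        logger.info(
            "dropped %d incomplete feature(s): %s",
            int(bad.sum()),
            list(frame.columns[bad])[:10],
        )
    return frame.loc[:, ~bad]


def preprocess_expression(
    bundle: DatasetBundle,
    metadata: pd.DataFrame,
    covariates: list[str],
    cv_percentile: float = 75.0,
) -> DatasetBundle:
    """Raw intensities -> log2+quantile normalize -> CV filter ->
    studentized residuals on covariates -> feature standardization."""
    data = log2_quantile_normalize(bundle.data)
    data, _ = cv_filter(data, cv_percentile)
    data = studentized_residualize(data, metadata, covariates)
    data = standardize_features(data)
    steps = [
        "log2_quantile_normalize",
        f"cv_filter(percentile={cv_percentile})",
        f"studentized_residualize({','.join(covariates)})",
        "standardize_features",
    ]
    return DatasetBundle(bundle.name, data, [*bundle.provenance, *steps])


def preprocess_traits(
    bundle: DatasetBundle,
    metadata: pd.DataFrame,
    covariates: list[str],
) -> DatasetBundle:
    """Trait table -> drop incomplete traits -> studentized residuals ->
    feature standardization (no log/quantile step for morphometrics)."""
    data = drop_incomplete_features(bundle.data)
    data = studentized_residualize(data, metadata, covariates)
    data = standardize_features(data)
    steps = [
        "drop_incomplete_features",
        f"studentized_residualize({','.join(covariates)})",
        "standardize_features",
    ]
    return DatasetBundle(bundle.name, data, [*bundle.provenance, *steps])
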