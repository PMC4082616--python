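"""Sparse k-means clustering with lasso-type feature weights.

Standard k-means partitions samples to minimize the within-cluster sum of
squares over *all* features.  Sparse k-means instead maximizes a weighted
between-cluster sum of squares (BCSS),

    max_{C, w}  sum_j w_j * BCSS_j(C)
    subject to  ||w||_2 <= 1,  ||w||_1 <= s,  w_j >= 0,

so that features which do not separate the clusters receive zero weight.
The L1 bound ``s`` controls sparsity: at ``s = sqrt(p)`` no feature is
thresholded out and the first iterate coincides with standard k-means on the
(uniformly weighted) data; as ``s`` decreases toward 1 the weight vector
concentrates on fewer features.

The optimization alternates (a) k-means with squared Euclidean distance on
the matrix whose feature ``j`` is scaled by ``sqrt(w_j)`` and (b) a
closed-form weight update (soft-thresholded BCSS, renormalized) until the
weights stabilize.  Random starts apply to the k-means step of the first
alternation; subsequent k-means runs are warm-started from the previous
partition's centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SparseKMeansParams",
    "SparseKMeans",
    "SparseKMeansResults",
    "bcss_per_feature",
    "update_weights",
    "fit_sparse_kmeans",
    "standard_kmeans",
]


def bcss_per_feature(matrix, labels) -> np.ndarray:
    """Per-feature between-cluster sum of squares for a given partition.

    BCSS_j = sum_i (x_ij - xbar_j)^2 - sum_c sum_{i in c} (x_ij - xbar_cj)^2,
    i.e. the total sum of squares minus the within-cluster sum of squares;
    TSS_j = WSS_j + BCSS_j holds per feature and every entry is >= 0.
    """
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2 or len(labels) != x.shape[0]:
        raise ValueError("labels must have one entry per sample row")
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if counts.min() < 1:
        raise ValueError("every cluster label must cover at least one sample")
    n = x.shape[0]
    grand = x.mean(axis=0)
    bcss = -n * grand**2
    for c in range(len(uniq)):
        mean_c = x[inv == c].mean(axis=0)
        bcss += counts[c] * mean_c**2
    return np.clip(bcss, 0.0, None)


def update_weights(bcss, s: float) -> np.ndarray:
    """Optimal feature weights for fixed BCSS under the L1/L2 constraints.

    Maximizes ``sum_j w_j * bcss_j`` subject to ``||w||_2 <= 1``,
    ``||w||_1 <= s`` and ``w >= 0``.  The solution is the soft-thresholded
    BCSS vector renormalized to unit L2 norm; the threshold is 0 when the
    L1 constraint is slack, otherwise found by bisection so that
    ``||w||_1 = s`` (within 1e-8).
    """
    b = np.asarray(bcss, dtype=float)
    if (b < 0).any():
        raise ValueError("BCSS entries must be non-negative")
    if s < 1.0:
        raise ValueError(f"L1 bound s must be >= 1, got {s}")
    p = b.size
    if not b.any():
        warnings.warn(
            "all-zero BCSS: weight update is degenerate, returning uniform weights",
            UserWarning,
            stacklevel=2,
        )
        return np.full(p, 1.0 / np.sqrt(p))
    b = b / b.max()  # weights are scale-invariant in b; guards underflow

    def w_of(delta: float) -> np.ndarray:
        u = np.clip(b - delta, 0.0, None)
        nrm = np.linalg.norm(u)
        return u / nrm if nrm > 0 else u

    w = w_of(0.0)
    if w.sum() <= s + 1e-8:
        return w
    lo, hi = 0.0, float(b.max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        l1 = w_of(mid).sum()
        if abs(l1 - s) <= 1e-8:
            lo = hi = mid
            break
        if l1 > s:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-14 * max(1.0, b.max()):
            break
    w = w_of(lo)  # lo side guarantees ||w||_1 >= s and a nonzero vector
    if w.sum() > s + 1e-8:  # nudge to the feasible side if bisection stopped short
        w = w_of(0.5 * (lo + hi))
    if w.sum() > s + 1e-8:
        # exact ties at max(b): ||w||_1 cannot reach s by thresholding alone;
        # keep the first floor(s^2) tied coordinates (deterministic tie-break)
        tied = np.flatnonzero(b == b.max())
        m = max(1, min(len(tied), int(np.floor(s * s + 1e-12))))
        w = np.zeros(p)
        w[tied[:m]] = 1.0 / np.sqrt(m)
    return w


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..k in order of first occurrence (deterministic)."""
    seen: dict = {}
    out = np.empty(labels.shape[0], dtype=int)
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen) + 1)
    return out


def _lloyd(z: np.ndarray, centers: np.ndarray, max_iter: int) -> np.ndarray:
    """Standard Lloyd iterations with squared Euclidean distance.

    Nearest-centroid ties break toward the lowest cluster index; an emptied
    cluster is re-seeded at the point farthest from its assigned centroid.
    """
    n, k = z.shape[0], centers.shape[0]
    z_sq = np.einsum("ij,ij->i", z, z)
    labels = None
    for _ in range(max_iter):
        d = z_sq[:, None] - 2.0 * (z @ centers.T) + np.einsum(
            "ij,ij->i", centers, centers
        )[None, :]
        new_labels = d.argmin(axis=1)
        own = d[np.arange(n), new_labels]
        for c in range(k):
            if not (new_labels == c).any():
                far = int(own.argmax())
                new_labels[far] = c
                own[far] = -np.inf
        if labels is not None and (new_labels == labels).all():
            break
        labels = new_labels
        centers = np.vstack([z[labels == c].mean(axis=0) for c in range(k)])
    return labels


def _single_run(mats, s_list, k, max_iter, weight_tol, rng):
    n = mats[0].shape[0]
    w = [np.full(m.shape[1], 1.0 / np.sqrt(m.shape[1])) for m in mats]
    labels = None
    converged = False
    n_iter = 0
    bcss_list = None
    history = []
    for it in range(max_iter):
        n_iter = it + 1
        z = np.hstack([m * np.sqrt(wd) for m, wd in zip(mats, w)])
        if labels is None:
            centers = z[rng.choice(n, size=k, replace=False)]
        else:
            centers = np.vstack([
                z[labels == c].mean(axis=0) if (labels == c).any()
                else z[rng.integers(n)]
                for c in range(k)
            ])
        labels = _lloyd(z, centers, max_iter)
        bcss_list = [bcss_per_feature(m, labels) for m in mats]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # all-zero BCSS nulls
            w_new = [update_weights(b, s) for b, s in zip(bcss_list, s_list)]
        num = sum(np.abs(wn - wo).sum() for wn, wo in zip(w_new, w))
        den = max(sum(np.abs(wo).sum() for wo in w), 1e-12)
        w = w_new
        history.append(float(sum(wd @ bd for wd, bd in zip(w, bcss_list))))
        if num / den < weight_tol:
            converged = True
            break
    objective = history[-1]
    return labels, w, bcss_list, objective, n_iter, converged, history


def _alternating_fit(
    mats: list[np.ndarray],
    s_list: list[float],
    k: int,
    n_starts: int = 20,
    max_iter: int = 20,
    weight_tol: float = 1e-4,
    seed=None,
):
    """Shared alternating optimizer for single and multi-dataset fits.

    Runs ``n_starts`` restarts of the alternation, each initialized by a
    random sample of k rows as centroids, and keeps the best final weighted
    objective.  Returns (labels 1-based, weight vectors, bcss vectors,
    objective, n_iter, converged).
    """
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("all datasets must share the same samples")
    if not 2 <= k <= n - 1:
        raise ValueError(f"need 2 <= k <= n-1, got k={k} with n={n}")
    concat = np.hstack(mats)
    if np.unique(concat, axis=0).shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of distinct sample rows")
    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_starts):
        run = _single_run(mats, s_list, k, max_iter, weight_tol,
                          np.random.default_rng(child))
        if best is None or run[3] > best[3]:
            best = run
    labels, w, bcss_list, objective, n_iter, converged, history = best
    return _canonical_labels(labels), w, bcss_list, objective, n_iter, converged, \
        history


def standard_kmeans(
    matrix, k: int, n_starts: int = 20, max_iter: int = 20, seed=None
) -> np.ndarray:
    """Plain (unweighted) k-means with the same starts/Lloyd machinery.

    This is the reduction target of sparse k-means at ``s = sqrt(p)``:
    equal feature weights make the weighted data a rescaled copy of the
    input, so the first sparse iterate coincides with this partition.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    best_labels, best_bcss = None, -np.inf
    for child in ss.spawn(n_starts):
        rng = np.random.default_rng(child)
        centers = x[rng.choice(n, size=k, replace=False)]
        labels = _lloyd(x, centers, max_iter)
        bcss = bcss_per_feature(x, labels).sum()
        if bcss > best_bcss:
            best_labels, best_bcss = labels, bcss
    return _canonical_labels(best_labels)


@dataclass
class SparseKMeansParams:
    """Tuning knobs of a single-dataset sparse k-means fit."""

    k: int
    s: float
    n_starts: int = 20
    max_iter: int = 20
    weight_tol: float = 1e-4

    def validate(self, n: int, p: int) -> None:
        if not 2 <= self.k <= n - 1:
            raise ValueError(f"need 2 <= k <= n-1, got k={self.k}, n={n}")
        if not 1.0 < self.s <= np.sqrt(p) + 1e-8:
            raise ValueError(f"need 1 < s <= sqrt(p)={np.sqrt(p):.3f}, got s={self.s}")


@dataclass
class SparseKMeansResults:
    """Fitted sparse k-means solution.

    Attributes
    ----------
    labels : pandas.Series
        1-based class assignment per sample (renumbered by first occurrence).
    weights : pandas.Series
        Non-negative per-feature weights, ``||w||_2 = 1``, ``||w||_1 <= s``.
    bcss : pandas.Series
        Per-feature between-cluster sum of squares at the fitted partition.
    objective : float
        The maximized weighted BCSS, ``sum_j w_j * BCSS_j``.
    """

    model: "SparseKMeans"
    k: int
    s: float
    labels: pd.Series
    weights: pd.Series
    bcss: pd.Series
    objective: float
    n_iter: int
    converged: bool
    seed: object = None
    gap: object = None  # GapInference attached by model selection
    extra: dict = field(default_factory=dict)

    @property
    def n_nonzero_weights(self) -> int:
        return int((self.weights.to_numpy() > 0).sum())

    @property
    def pct_nonzero_weights(self) -> float:
        return 100.0 * self.n_nonzero_weights / len(self.weights)

    @property
    def max_weight_feature(self) -> tuple:
        j = self.weights.idxmax()
        return j, float(self.weights.loc[j])

    @property
    def class_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def weighted_pca(self, n_components: int = 2):
        from .characterize import weighted_pca

        return weighted_pca(
            self.model.data, self.weights.to_numpy(), n_components=n_components
        )

    def summary(self) -> str:
        feat, wmax = self.max_weight_feature
        lines = [
            f"Sparse k-means clustering: {self.model.name}",
            f"  n samples / features     {len(self.labels)} / {len(self.weights)}",
            f"  k classes                {self.k}",
            "  class sizes              "
            + ", ".join(f"{c}: {n}" for c, n in self.class_sizes.items()),
            f"  tuning parameter s       {self.s:.4g}",
            f"  non-zero weights         {self.n_nonzero_weights} "
            f"({self.pct_nonzero_weights:.1f}%)",
            f"  max-weight feature       {feat} ({wmax:.2f})",
            f"  objective (wtd BCSS)     {self.objective:.4f}",
            f"  converged                {self.converged} ({self.n_iter} iter)",
        ]
        if self.gap is not None:
            g = self.gap
            lines += [
                f"  gap statistic            {g.gap:.3f} ± {g.sd:.3f}",
                f"  95% CI                   {g.ci95[0]:.3f}-{g.ci95[1]:.3f}",
                f"  p-value                  {g.p_value:.3g}",
            ]
        return "\n".join(lines)


class SparseKMeans:
    """Sparse k-means model for one standardized samples x features matrix.

    Parameters
    ----------
    data : DataFrame or array, samples x features
        Feature-standardized matrix (mean 0, SD 1 per feature) as produced
        by the preprocessing pipeline.
    name : str, optional
        Label used in summaries.
    """

    def __init__(self, data, name: str | None = None):
        if isinstance(data, pd.DataFrame):
            self.data = data
        else:
            self.data = pd.DataFrame(np.asarray(data, dtype=float))
        if self.data.isna().any(axis=None):
            raise ValueError("input matrix contains missing values")
        self.name = name or "dataset"

    @classmethod
    def from_bundle(cls, bundle) -> "SparseKMeans":
        return cls(bundle.data, name=bundle.name)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def fit(
        self,
        k: int,
        s: float,
        n_starts: int = 20,
        max_iter: int = 20,
        weight_tol: float = 1e-4,
        seed=None,
    ) -> SparseKMeansResults:
        """Fit the sparse k-means solution at a fixed (k, s)."""
        params = SparseKMeansParams(k, s, n_starts, max_iter, weight_tol)
        params.validate(self.n_samples, self.n_features)
        labels, ws, bcss, obj, n_iter, conv, history = _alternating_fit(
            [self.data.to_numpy(dtype=float)],
            [s],
            k,
            n_starts=n_starts,
            max_iter=max_iter,
            weight_tol=weight_tol,
            seed=seed,
        )
        if not conv:
            warnings.warn(
                f"sparse k-means did not converge in {max_iter} iterations; "
                "returning best iterate",
                UserWarning,
                stacklevel=2,
            )
        return SparseKMeansResults(
            model=self,
            k=k,
            s=s,
            labels=pd.Series(labels, index=self.data.index, name="class"),
            weights=pd.Series(ws[0], index=self.data.columns, name="weight"),
            bcss=pd.Series(bcss[0], index=self.data.columns, name="bcss"),
            objective=obj,
            n_iter=n_iter,
            converged=conv,
            seed=seed,
            extra={"objective_history": history},
        )

    def select(
        self,
        k_range: tuple[int, int] = (2, 5),
        n_tuning: int = 50,
        n_permutations: int = 25,
        n_starts: int = 20,
        max_iter: int = 20,
        seed=None,
    ):
        """Gap-statistic search over the (k, s) grid; see
        :func:`sparsekm.selection.select_model`."""
        from .selection import select_model

        return select_model(
            self,
            k_range=k_range,
            n_tuning=n_tuning,
            n_permutations=n_permutations,
            n_starts=n_starts,
            max_iter=max_iter,
            seed=seed,
        )


def fit_sparse_kmeans(
    matrix, k: int, s: float, n_starts: int = 20, max_iter: int = 20,
    weight_tol: float = 1e-4, seed=None,
) -> SparseKMeansResults:
    """Functional convenience wrapper around :meth:`SparseKMeans.fit`."""
    return SparseKMeans(matrix).fit(
        k, s, n_starts=n_starts, max_iter=max_iter, weight_tol=weight_tol, seed=seed
    )
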