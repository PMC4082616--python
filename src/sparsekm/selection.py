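"""Gap-statistic model selection and inference for sparse k-means.

The number of classes k and the sparsity bound s are chosen jointly by
maximizing the gap statistic over a (k, s) grid:

    gap(k, s) = log O(X; k, s) - mean_b log O(X*_b; k, s)

where O is the maximized weighted BCSS objective and X*_b are null matrices
obtained by independently permuting the samples within each feature.  The
permutation SD of the null log-objectives yields a normal-approximation
z = gap/sd, an upper-tail p-value and a 95% CI (gap ± 1.96 sd).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sparse_kmeans import SparseKMeans, SparseKMeansResults

__all__ = [
    "permute_within_features",
    "gap_statistic",
    "gap_inference",
    "select_model",
    "GapInference",
    "GapGrid",
    "GapSearchResults",
]

logger = logging.getLogger(__name__)


def permute_within_features(matrix, seed=None):
    """Independently permute the samples within each feature (gap null).

    Column multisets (hence per-feature means and SDs) are preserved; any
    association between features and any sample structure is destroyed.
    """
    rng = np.random.default_rng(seed)
    frame = matrix if isinstance(matrix, pd.DataFrame) else None
    x = np.array(matrix, dtype=float, copy=True)
    n = x.shape[0]
    for j in range(x.shape[1]):
        x[:, j] = x[rng.permutation(n), j]
    if frame is not None:
        return pd.DataFrame(x, index=frame.index, columns=frame.columns)
    return x


@dataclass
class GapInference:
    """Normal-approximation inference for a gap statistic."""

    gap: float
    sd: float
    z: float
    p_value: float
    ci95: tuple[float, float]
    degenerate: bool = False

    def __str__(self) -> str:
        flag = " (degenerate: sd = 0)" if self.degenerate else ""
        return (
            f"gap = {self.gap:.3f} ± {self.sd:.3f}, "
            f"95% CI {self.ci95[0]:.3f}-{self.ci95[1]:.3f}, "
            f"p = {self.p_value:.3g}{flag}"
        )


def gap_inference(gap: float, sd: float) -> GapInference:
    """z = gap/sd, upper-tail standard-normal p, and gap ± 1.96 sd."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        p = 0.0 if gap > 0 else 1.0
        return GapInference(gap, sd, np.inf if gap > 0 else -np.inf, p,
                            (gap, gap), degenerate=True)
    z = gap / sd
    return GapInference(
        gap, sd, z, float(norm.sf(z)), (gap - 1.96 * sd, gap + 1.96 * sd)
    )


def _fit_objective(matrix, k, s, n_starts, max_iter, seed) -> float:
    from .sparse_kmeans import _alternating_fit

    x = np.asarray(matrix, dtype=float)
    _, _, _, obj, _, _, _ = _alternating_fit(
        [x], [s], k, n_starts=n_starts, max_iter=max_iter, seed=seed
    )
    return obj


def gap_statistic(
    matrix,
    k: int,
    s: float,
    n_permutations: int = 25,
    n_starts: int = 20,
    max_iter: int = 20,
    seed=None,
    _nulls=None,
    _null_seeds=None,
) -> tuple[float, float]:
    """Gap statistic and permutation SD at a single (k, s).

    ``gap = log(observed objective) - mean_b log(null objective_b)``;
    ``sd`` is the sample SD of the null log-objectives.  The same k, s,
    starts and iteration cap are used for observed and null fits.
    """
    ss = np.random.SeedSequence(seed)
    perm_ss, obs_ss, null_ss = ss.spawn(3)
    if _nulls is None:
        perm_children = perm_ss.spawn(n_permutations)
        _nulls = [
            permute_within_features(matrix, np.random.default_rng(c))
            for c in perm_children
        ]
    if _null_seeds is None:
        _null_seeds = null_ss.generate_state(len(_nulls)) % (2**31)
    obs_seed = int(obs_ss.generate_state(1)[0] % (2**31))
    obj = _fit_objective(matrix, k, s, n_starts, max_iter, obs_seed)
    log_nulls = []
    for b, null in enumerate(_nulls):
        null_obj = _fit_objective(null, k, s, n_starts, max_iter, int(_null_seeds[b]))
        attempts = 0
        while null_obj <= 0 and attempts < 5:
            logger.info("zero null objective at permutation %d: redrawing", b)
            redraw = permute_within_features(
                matrix, np.random.default_rng(perm_ss.spawn(1)[0])
            )
            null_obj = _fit_objective(redraw, k, s, n_starts, max_iter,
                                      int(_null_seeds[b]))
            attempts += 1
        log_nulls.append(np.log(null_obj))
    log_nulls = np.asarray(log_nulls)
    gap = float(np.log(obj) - log_nulls.mean())
    sd = float(log_nulls.std(ddof=1)) if len(log_nulls) > 1 else 0.0
    return gap, sd


@dataclass
class GapGrid:
    """Full gap-statistic grid plus the selected optimum.

    ``entries`` has one row per (k, s) with columns
    ``k, s, gap, sd, objective``; ``selected`` is the (k, s) attaining the
    grid-maximal gap (ties broken toward smaller k, then smaller s).
    """

    entries: pd.DataFrame
    selected: tuple[int, float]
    n_permutations: int

    @property
    def best_entry(self) -> pd.Series:
        k, s = self.selected
        mask = (self.entries["k"] == k) & (self.entries["s"] == s)
        return self.entries[mask].iloc[0]

    def best_inference(self) -> GapInference:
        e = self.best_entry
        return gap_inference(float(e["gap"]), float(e["sd"]))


def _tuning_grid(p: int, n_tuning: int) -> np.ndarray:
    """Linear s grid over (1.2, sqrt(p)]."""
    hi = np.sqrt(p)
    if hi <= 1.2:
        raise ValueError(f"degenerate grid: sqrt(p)={hi:.3f} <= 1.2 (p={p})")
    if n_tuning == 1:
        return np.array([hi])
    return np.linspace(1.2, hi, n_tuning)


def select_model(
    model,
    k_range: tuple[int, int] = (2, 5),
    n_tuning: int = 50,
    n_permutations: int = 25,
    n_starts: int = 20,
    max_iter: int = 20,
    seed=None,
    s_values=None,
) -> "GapSearchResults":
    """Grid-search (k, s) by maximal gap statistic.

    ``model`` is a :class:`~sparsekm.sparse_kmeans.SparseKMeans` instance or
    a samples x features matrix.  The permuted null matrices are generated
    once and reused across the whole grid (common random numbers); each
    (k, permutation) fit draws from an independent seed stream.
    """
    if not isinstance(model, SparseKMeans):
        model = SparseKMeans(model)
    n, p = model.n_samples, model.n_features
    if p < 2:
        raise ValueError(f"degenerate grid: need p >= 2 features, got {p}")
    k_lo, k_hi = k_range
    if not (2 <= k_lo <= k_hi <= n - 1):
        raise ValueError(f"k_range {k_range} must lie within [2, n-1]")
    s_grid = np.asarray(s_values, dtype=float) if s_values is not None else \
        _tuning_grid(p, n_tuning)

    ss = np.random.SeedSequence(seed)
    perm_ss, obs_ss, null_ss = ss.spawn(3)
    x = model.data
    nulls = [
        permute_within_features(x, np.random.default_rng(c))
        for c in perm_ss.spawn(n_permutations)
    ]
    ks = list(range(k_lo, k_hi + 1))
    obs_seeds = obs_ss.generate_state(len(ks)) % (2**31)
    null_seeds = null_ss.generate_state(len(ks) * n_permutations).reshape(
        len(ks), n_permutations
    ) % (2**31)

    rows = []
    for ki, k in enumerate(ks):
        # cache null log-objectives per (k, s)
        for s in s_grid:
            obj = _fit_objective(x, k, s, n_starts, max_iter, int(obs_seeds[ki]))
            log_nulls = np.array([
                np.log(_fit_objective(nulls[b], k, s, n_starts, max_iter,
                                      int(null_seeds[ki, b])))
                for b in range(n_permutations)
            ])
            gap = float(np.log(obj) - log_nulls.mean())
            sd = float(log_nulls.std(ddof=1)) if n_permutations > 1 else 0.0
            rows.append({"k": k, "s": float(s), "gap": gap, "sd": sd,
                         "objective": obj})
    entries = pd.DataFrame(rows)
    # argmax gap; ties toward smaller k then smaller s
    best = entries.sort_values(["gap", "k", "s"],
                               ascending=[False, True, True]).iloc[0]
    grid = GapGrid(entries, (int(best["k"]), float(best["s"])), n_permutations)
    fit = model.fit(int(best["k"]), float(best["s"]), n_starts=n_starts,
                    max_iter=max_iter, seed=int(obs_seeds[ks.index(int(best["k"]))]))
    fit.gap = grid.best_inference()
    return GapSearchResults(model=model, grid=grid, results=fit)


@dataclass
class GapSearchResults:
    """Outcome of the gap-statistic grid search.

    ``grid`` holds every (k, s) evaluation; ``results`` is the refit
    solution at the selected optimum with its gap inference attached.
    """

    model: SparseKMeans
    grid: GapGrid
    results: SparseKMeansResults
    extra: dict = field(default_factory=dict)

    @property
    def best_k(self) -> int:
        return self.grid.selected[0]

    @property
    def best_s(self) -> float:
        return self.grid.selected[1]

    @property
    def inference(self) -> GapInference:
        return self.results.gap

    def summary(self) -> str:
        return (
            f"Gap-statistic model selection: {self.model.name}\n"
            f"  grid                     k = {sorted(int(k) for k in self.grid.entries['k'].unique())}"
            f" x {self.grid.entries.groupby('k').size().iloc[0]} tuning values, "
            f"{self.grid.n_permutations} permutations\n"
            f"  selected (k, s)          ({self.best_k}, {self.best_s:.4g})\n"
            + self.results.summary()
        )
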