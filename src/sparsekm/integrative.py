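"""Integrative sparse k-means: one shared partition across several datasets.

Each data source (e.g. blood expression, dura expression, cranial
morphometrics) keeps its own feature-weight vector and sparsity bound, but
all sources share a single sample partition.  Three modifications relative
to the single-dataset method:

1. **Equal-footing scaling** -- before clustering, each standardized dataset
   is multiplied by sqrt(T / TSS_d) so all total sums of squares match the
   first dataset's; otherwise the largest dataset would dominate the joint
   objective.
2. **Feature-count-relative tuning** -- a single tuning parameter
   t in (0, 1] maps to per-dataset L1 bounds s_d = 1 + t (sqrt(p_d) - 1),
   so the enforced sparsity level is comparable across datasets of very
   different sizes.  t = 1 gives s_d = sqrt(p_d): no sparsity anywhere.
3. **Within-dataset object permutation null** -- the gap-statistic null
   permutes whole sample rows independently within each dataset.  This
   preserves every dataset's internal cluster structure and destroys only
   the cross-dataset alignment, so a significant integrative gap evidences
   *joint* structure rather than structure in any single dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundles import DatasetBundle, check_aligned
from .selection import GapGrid, GapInference, gap_inference
from .sparse_kmeans import _alternating_fit

__all__ = [
    "MultiDataset",
    "scale_datasets",
    "IntegrativeSparseKMeans",
    "IntegrativeResults",
    "permute_within_datasets",
    "integrative_gap",
]


def _total_ss(x: np.ndarray) -> float:
    return float(((x - x.mean(axis=0)) ** 2).sum())


@dataclass
class MultiDataset:
    """Aligned, equal-total-SS-scaled collection of dataset bundles."""

    bundles: list[DatasetBundle]
    scale_factors: list[float]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bundles]

    def matrices(self) -> list[np.ndarray]:
        return [b.values() for b in self.bundles]


def scale_datasets(bundles: list[DatasetBundle]) -> MultiDataset:
    """Scale each dataset by sqrt(T / TSS_d), T = first dataset's total SS.

    Post-condition: all total sums of squares agree within 1e-8 (relative).
    """
    check_aligned(bundles)
    tss = [_total_ss(b.values()) for b in bundles]
    if any(t <= 0 for t in tss):
        bad = bundles[tss.index(min(tss))].name
        raise ValueError(f"dataset {bad!r} has zero total sum of squares")
    target = tss[0]
    factors = [float(np.sqrt(target / t)) for t in tss]
    scaled = [
        b.with_data(b.data * f, f"scale_total_ss(x{f:.6g})")
        for b, f in zip(bundles, factors)
    ]
    return MultiDataset(scaled, factors)


def permute_within_datasets(multi: MultiDataset, seed=None) -> MultiDataset:
    """Null for the integrative gap: permute whole sample rows per dataset.

    Each dataset's rows are shuffled by an independent permutation, keeping
    its internal structure intact while destroying cross-dataset sample
    alignment.  With a single dataset the null is vacuous (any one dataset
    is invariant up to row order) and a warning is raised.  For very small
    n the identity permutation is excluded.
    """
    if len(multi.bundles) < 2:
        warnings.warn(
            "within-dataset permutation of a single dataset is vacuous",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out = []
    for b in multi.bundles:
        n = b.n_samples
        perm = rng.permutation(n)
        if n <= 5:
            while (perm == np.arange(n)).all():
                perm = rng.permutation(n)
        data = pd.DataFrame(
            b.values()[perm], index=b.data.index, columns=b.data.columns
        )
        out.append(b.with_data(data, "permute_rows"))
    return MultiDataset(out, multi.scale_factors)


def _s_bounds(ps: list[int], t: float) -> list[float]:
    if not 0 < t <= 1:
        raise ValueError(f"tuning parameter t must lie in (0, 1], got {t}")
    return [1.0 + t * (np.sqrt(p) - 1.0) for p in ps]


@dataclass
class IntegrativeResults:
    """Fitted integrative solution: shared labels, per-dataset weights."""

    model: "IntegrativeSparseKMeans"
    k: int
    t: float
    labels: pd.Series
    weights: dict[str, pd.Series]
    bcss: dict[str, pd.Series]
    objective: float
    s_bounds: dict[str, float]
    n_iter: int
    converged: bool
    seed: object = None
    gap: GapInference | None = None
    extra: dict = field(default_factory=dict)

    @property
    def class_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def n_nonzero_weights(self, name: str) -> int:
        return int((self.weights[name].to_numpy() > 0).sum())

    def pct_nonzero_weights(self, name: str) -> float:
        return 100.0 * self.n_nonzero_weights(name) / len(self.weights[name])

    def max_weight_feature(self, name: str) -> tuple:
        w = self.weights[name]
        j = w.idxmax()
        return j, float(w.loc[j])

    def summary(self) -> str:
        names = list(self.weights)
        lines = [
            "Integrative sparse k-means clustering: " + "-".join(names),
            f"  k classes                {self.k}",
            "  class sizes              "
            + ", ".join(f"{c}: {n}" for c, n in self.class_sizes.items()),
            f"  tuning parameter t       {self.t:.4g}",
        ]
        for name in names:
            feat, wmax = self.max_weight_feature(name)
            lines.append(
                f"  {name}: non-zero weights {self.n_nonzero_weights(name)} "
                f"({self.pct_nonzero_weights(name):.1f}%), "
                f"max-weight feature {feat} ({wmax:.2f}), "
                f"s_d = {self.s_bounds[name]:.4g}"
            )
        lines.append(f"  joint objective          {self.objective:.4f}")
        if self.gap is not None:
            g = self.gap
            lines += [
                f"  gap statistic            {g.gap:.3f} ± {g.sd:.3f}",
                f"  95% CI                   {g.ci95[0]:.3f}-{g.ci95[1]:.3f}",
                f"  p-value                  {g.p_value:.3g}",
            ]
        return "\n".join(lines)


class IntegrativeSparseKMeans:
    """Integrative sparse k-means over >= 1 aligned, standardized datasets.

    Parameters
    ----------
    bundles : list of DatasetBundle (or DataFrames / arrays)
        Feature-standardized sources sharing sample ids and ordering.
        Equal-total-SS scaling is applied at construction.
    """

    def __init__(self, bundles, names: list[str] | None = None):
        prepared = []
        for i, b in enumerate(bundles):
            if isinstance(b, DatasetBundle):
                prepared.append(b)
            else:
                frame = b if isinstance(b, pd.DataFrame) else pd.DataFrame(
                    np.asarray(b, dtype=float)
                )
                prepared.append(
                    DatasetBundle(names[i] if names else f"dataset{i + 1}", frame)
                )
        if names:
            prepared = [
                DatasetBundle(nm, b.data, b.provenance)
                for nm, b in zip(names, prepared)
            ]
        # arrays carry a default RangeIndex; align it across sources
        if not all(isinstance(b, DatasetBundle) for b in bundles):
            ref = prepared[0].data.index
            prepared = [
                DatasetBundle(b.name, b.data.set_axis(ref, axis=0), b.provenance)
                for b in prepared
            ]
        self.multi = scale_datasets(prepared)

    @property
    def names(self) -> list[str]:
        return self.multi.names

    @property
    def n_samples(self) -> int:
        return self.multi.bundles[0].n_samples

    def fit(
        self,
        k: int,
        t: float,
        n_starts: int = 20,
        max_iter: int = 20,
        weight_tol: float = 1e-4,
        seed=None,
        _multi: MultiDataset | None = None,
    ) -> IntegrativeResults:
        """Fit the shared-partition solution at fixed (k, t).

        The per-dataset L1 bounds are s_d = 1 + t (sqrt(p_d) - 1); k-means
        runs on the horizontal concatenation of the sqrt(w_d)-scaled
        datasets while each dataset's weights are updated separately from
        its own per-feature BCSS.
        """
        multi = _multi if _multi is not None else self.multi
        mats = multi.matrices()
        s_list = _s_bounds([m.shape[1] for m in mats], t)
        labels, ws, bcss, obj, n_iter, conv, history = _alternating_fit(
            mats, s_list, k,
            n_starts=n_starts, max_iter=max_iter, weight_tol=weight_tol, seed=seed,
        )
        names = multi.names
        index = multi.bundles[0].data.index
        return IntegrativeResults(
            model=self,
            k=k,
            t=t,
            labels=pd.Series(labels, index=index, name="class"),
            weights={
                nm: pd.Series(w, index=b.data.columns, name="weight")
                for nm, w, b in zip(names, ws, multi.bundles)
            },
            bcss={
                nm: pd.Series(v, index=b.data.columns, name="bcss")
                for nm, v, b in zip(names, bcss, multi.bundles)
            },
            objective=obj,
            s_bounds=dict(zip(names, s_list)),
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
        t_values=None,
    ) -> "IntegrativeGapSearchResults":
        """Grid-search (k, t) by maximal integrative gap statistic.

        The null reuses one set of within-dataset-permuted copies across the
        whole grid; inference at the selected entry is the usual normal
        approximation.
        """
        n = self.n_samples
        k_lo, k_hi = k_range
        if not (2 <= k_lo <= k_hi <= n - 1):
            raise ValueError(f"k_range {k_range} must lie within [2, n-1]")
        if t_values is not None:
            t_grid = np.asarray(t_values, dtype=float)
        else:
            t_grid = np.linspace(1.0 / n_tuning, 1.0, n_tuning)
        ss = np.random.SeedSequence(seed)
        perm_ss, obs_ss, null_ss = ss.spawn(3)
        nulls = [
            permute_within_datasets(self.multi, np.random.default_rng(c))
            for c in perm_ss.spawn(n_permutations)
        ]
        ks = list(range(k_lo, k_hi + 1))
        obs_seeds = obs_ss.generate_state(len(ks)) % (2**31)
        null_seeds = null_ss.generate_state(len(ks) * n_permutations).reshape(
            len(ks), n_permutations
        ) % (2**31)
        rows = []
        for ki, k in enumerate(ks):
            for t in t_grid:
                obj = self.fit(k, float(t), n_starts=n_starts, max_iter=max_iter,
                               seed=int(obs_seeds[ki])).objective
                log_nulls = np.array([
                    np.log(self.fit(k, float(t), n_starts=n_starts,
                                    max_iter=max_iter,
                                    seed=int(null_seeds[ki, b]),
                                    _multi=nulls[b]).objective)
                    for b in range(n_permutations)
                ])
                gap = float(np.log(obj) - log_nulls.mean())
                sd = float(log_nulls.std(ddof=1)) if n_permutations > 1 else 0.0
                rows.append({"k": k, "s": float(t), "gap": gap, "sd": sd,
                             "objective": obj})
        entries = pd.DataFrame(rows)
        best = entries.sort_values(["gap", "k", "s"],
                                   ascending=[False, True, True]).iloc[0]
        grid = GapGrid(entries, (int(best["k"]), float(best["s"])), n_permutations)
        fit = self.fit(
            int(best["k"]), float(best["s"]), n_starts=n_starts, max_iter=max_iter,
            seed=int(obs_seeds[ks.index(int(best["k"]))]),
        )
        fit.gap = grid.best_inference()
        return IntegrativeGapSearchResults(model=self, grid=grid, results=fit)


def integrative_gap(
    model: IntegrativeSparseKMeans,
    k: int,
    t: float,
    n_permutations: int = 25,
    n_starts: int = 20,
    max_iter: int = 20,
    seed=None,
) -> tuple[GapInference, dict]:
    """Integrative gap statistic at a single (k, t) with inference.

    gap = log(joint objective observed) - mean_b log(joint objective on
    within-dataset-permuted null b); sd over the null log-objectives.
    """
    res = model.select(
        k_range=(k, k),
        n_permutations=n_permutations,
        n_starts=n_starts,
        max_iter=max_iter,
        seed=seed,
        t_values=[t],
    )
    e = res.grid.best_entry
    return gap_inference(float(e["gap"]), float(e["sd"])), {
        "objective": float(e["objective"]),
        "k": k,
        "t": t,
    }


@dataclass
class IntegrativeGapSearchResults:
    """Outcome of the integrative (k, t) grid search."""

    model: IntegrativeSparseKMeans
    grid: GapGrid
    results: IntegrativeResults
    extra: dict = field(default_factory=dict)

    @property
    def best_k(self) -> int:
        return self.grid.selected[0]

    @property
    def best_t(self) -> float:
        return self.grid.selected[1]

    @property
    def inference(self) -> GapInference:
        return self.results.gap

    def summary(self) -> str:
        return (
            "Integrative gap-statistic model selection\n"
            f"  selected (k, t)          ({self.best_k}, {self.best_t:.4g})\n"
            + self.results.summary()
        )
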