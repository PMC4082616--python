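"""Synthetic multi-source cohorts with known subtype structure.

Emulates the study design this package targets: a pediatric cohort of
n = 44 patients with two whole-genome expression sources (blood and dura,
~11804 probes each, BeadChip-like log2 intensities with additive covariate
effects) and a 24-trait posterior-fossa morphometric table.  A planted
partition of 2-5 classes is carried by a subset of "informative" features
per source; the partition may be shared across sources (joint structure) or
drawn independently per source.  Expression sources are returned on the raw
intensity scale (2^x of the latent log2 values) so the preprocessing stack
is exercised end to end.

Everything downstream can therefore be scored against exact ground truth:
the planted labels, the informative-feature masks, and the covariate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundles import DatasetBundle

__all__ = [
    "SourceSpec",
    "CohortSpec",
    "CohortTruth",
    "generate_cohort",
    "generate_clinical_table",
]

EXPRESSION_COVARIATES = ["age_at_surgery", "sex", "race", "surgeon"]
TRAIT_COVARIATES = ["age_at_mri", "sex", "race"]


@dataclass
class SourceSpec:
    """One data source of the cohort.

    ``scale`` is ``"log2-intensity"`` for expression-like sources (returned
    as raw 2^x intensities) or ``"trait"`` for continuous morphometrics.
    ``dura_like`` sources additionally receive the RIN covariate effect.
    """

    name: str
    n_features: int
    scale: str = "log2-intensity"
    informative_fraction: float = 0.1
    dura_like: bool = False

    def __post_init__(self):
        if self.scale not in ("log2-intensity", "trait"):
            raise ValueError(f"unknown source scale {self.scale!r}")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in [0, 1]")


def _default_sources() -> list[SourceSpec]:
    return [
        SourceSpec("blood", 11804, "log2-intensity"),
        SourceSpec("dura", 11804, "log2-intensity", dura_like=True),
        SourceSpec("cranial", 24, "trait"),
    ]


def _default_covariate_effects() -> dict[str, float]:
    return {
        "age_at_surgery": 0.2,
        "age_at_mri": 0.2,
        "sex": 0.3,
        "race": 0.3,
        "surgeon": 0.2,
    }


@dataclass
class CohortSpec:
    """Study design of a synthetic cohort.

    Defaults mirror the targeted study: 44 samples, blood + dura expression
    sources of 11804 probes and a 24-trait morphometric source, a planted
    2-class partition shared across sources, effect size delta = 1.5
    within-class SDs on 10% of features, and covariate effects on the log2
    scale.  ``covariate_effects`` magnitudes apply to standardized covariate
    values; ``rin_effect`` applies only to dura-like sources.
    """

    n_samples: int = 44
    sources: list[SourceSpec] = field(default_factory=_default_sources)
    k_true: int = 2
    effect_size: float = 1.5
    joint_structure: bool = True
    covariate_effects: dict[str, float] = field(
        default_factory=_default_covariate_effects
    )
    rin_effect: float = 0.3
    missing_rate: float = 0.18
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n_samples < self.k_true:
            raise ValueError(
                f"n_samples={self.n_samples} must be >= k_true={self.k_true}"
            )
        if self.effect_size < 0:
            raise ValueError("effect size delta must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        for src in self.sources:
            src.__post_init__()


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    partitions: dict[str, np.ndarray]  # per source, labels in 1..k_true
    informative_masks: dict[str, np.ndarray]
    covariate_table: pd.DataFrame
    effect_size: float

    def partition_of(self, source: str) -> np.ndarray:
        return self.partitions[source]


def _draw_partition(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Near-balanced class labels (multinomial, equal probabilities);
    redrawn until every class is occupied."""
    if k == 1:
        return np.ones(n, dtype=int)
    while True:
        labels = rng.integers(1, k + 1, size=n)
        if len(np.unique(labels)) == k:
            return labels


def _covariate_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    age_surgery = rng.uniform(1.0, 18.0, size=n)
    table = pd.DataFrame(
        {
            "age_at_surgery": age_surgery,
            "age_at_mri": np.clip(age_surgery - rng.uniform(0.0, 0.5, size=n),
                                  0.5, None),
            "sex": rng.choice(["M", "F"], size=n, p=[0.636, 0.364]),
            "race": rng.choice(["white", "aa"], size=n, p=[0.705, 0.295]),
            "surgeon": rng.choice(["A", "B"], size=n),
            "rin": rng.uniform(6.0, 10.0, size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return table


def _standardized_numeric(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding (dummies for categoricals), each column z-scored."""
    num = {}
    for c in covariates.columns:
        col = covariates[c]
        v = (
            pd.get_dummies(col, drop_first=True, dtype=float).iloc[:, 0]
            if col.dtype == object
            else col.astype(float)
        )
        sd = v.std(ddof=1)
        num[c] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(num, index=covariates.index)


def _class_offsets(
    rng: np.random.Generator, n_informative: int, k: int, delta: float
) -> np.ndarray:
    """Per informative feature, an offset of 0 or delta per class, never
    constant across classes, so some class pair differs by delta."""
    if k == 1 or n_informative == 0:
        return np.zeros((n_informative, k))
    a = rng.integers(0, 2, size=(n_informative, k))
    bad = (a == a[:, :1]).all(axis=1)
    while bad.any():
        a[bad] = rng.integers(0, 2, size=(int(bad.sum()), k))
        bad = (a == a[:, :1]).all(axis=1)
    return delta * a


def _source_matrix(
    rng: np.random.Generator,
    src: SourceSpec,
    spec: CohortSpec,
    labels: np.ndarray,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray]:
    n, p = spec.n_samples, src.n_features
    expression = src.scale == "log2-intensity"
    baseline = rng.normal(8.0, 2.0, size=p) if expression else rng.normal(0.0, 2.0, p)
    latent = baseline[None, :] + rng.normal(0.0, 1.0, size=(n, p))

    n_inf = int(round(src.informative_fraction * p))
    mask = np.zeros(p, dtype=bool)
    if n_inf:
        mask[rng.choice(p, size=n_inf, replace=False)] = True
        offsets = _class_offsets(rng, n_inf, spec.k_true, spec.effect_size)
        latent[:, mask] += offsets[:, labels - 1].T

    cov_names = EXPRESSION_COVARIATES if expression else TRAIT_COVARIATES
    z = _standardized_numeric(covariates[cov_names])
    effects = {c: spec.covariate_effects.get(c, 0.0) for c in cov_names}
    if expression and src.dura_like and spec.rin_effect:
        z = z.join(_standardized_numeric(covariates[["rin"]]))
        effects["rin"] = spec.rin_effect
    for c, mag in effects.items():
        if mag:
            beta = rng.normal(0.0, mag, size=p)
            latent += np.outer(z[c].to_numpy(), beta)

    values = np.exp2(latent) if expression else latent
    prefix = "probe" if expression else "trait"
    frame = pd.DataFrame(
        values,
        index=covariates.index,
        columns=[f"{src.name}_{prefix}{j + 1}" for j in range(p)],
    )
    return frame, mask


def generate_cohort(spec: CohortSpec) -> tuple[list[DatasetBundle], CohortTruth]:
    """Generate the cohort's data sources and their ground truth.

    Seeding is hierarchical: one stream for covariates, one for the planted
    partition(s), one per source (in order), and one reserved for the
    clinical table -- so adding a source does not perturb earlier sources.
    Bit-identical outputs for a fixed ``spec.seed``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    cov_ss, part_ss, clin_ss, *src_ss = root.spawn(3 + len(spec.sources))
    del clin_ss  # consumed by generate_clinical_table

    covariates = _covariate_table(np.random.default_rng(cov_ss), spec.n_samples)
    part_rng = np.random.default_rng(part_ss)
    if spec.joint_structure:
        shared = _draw_partition(part_rng, spec.n_samples, spec.k_true)
        partitions = {src.name: shared.copy() for src in spec.sources}
    else:
        partitions = {
            src.name: _draw_partition(part_rng, spec.n_samples, spec.k_true)
            for src in spec.sources
        }

    bundles, masks = [], {}
    for src, child in zip(spec.sources, src_ss):
        frame, mask = _source_matrix(
            np.random.default_rng(child), src, spec, partitions[src.name], covariates
        )
        bundles.append(DatasetBundle(src.name, frame, [f"simulate:{src.scale}"]))
        masks[src.name] = mask
    truth = CohortTruth(partitions, masks, covariates, spec.effect_size)
    return bundles, truth


def generate_clinical_table(
    spec: CohortSpec,
    truth: CohortTruth,
    n_binary: int = 4,
    n_continuous: int = 2,
    n_associated: int = 2,
    association_strength: float = 1.0,
) -> pd.DataFrame:
    """Questionnaire-style clinical table with missingness.

    The first ``n_associated`` variables (binary first, then continuous) are
    associated with the planted partition of the first source at
    ``association_strength`` (log-odds shift for binary variables, a shift
    of that many SDs for continuous ones); the rest are pure noise.
    Entries are set missing independently at ``spec.missing_rate``
    (missingness independent of class).
    """
    if not 0.0 <= spec.missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    root = np.random.SeedSequence(spec.seed)
    _, _, clin_ss, *_ = root.spawn(3 + len(spec.sources))
    rng = np.random.default_rng(clin_ss)
    n = spec.n_samples
    labels = next(iter(truth.partitions.values()))
    in_class1 = (labels == 1).astype(float)

    data = {}
    assoc_left = n_associated
    for j in range(n_binary):
        shift = association_strength if assoc_left > 0 else 0.0
        assoc_left -= 1
        logit = -0.2 + shift * in_class1
        prob = 1.0 / (1.0 + np.exp(-logit))
        data[f"clin_bin{j + 1}"] = np.where(rng.uniform(size=n) < prob, "yes", "no")
    for j in range(n_continuous):
        shift = association_strength if assoc_left > 0 else 0.0
        assoc_left -= 1
        data[f"clin_cont{j + 1}"] = rng.normal(0.0, 1.0, size=n) + shift * in_class1

    table = pd.DataFrame(data, index=truth.covariate_table.index, dtype=object)
    if spec.missing_rate > 0:
        holes = rng.uniform(size=table.shape) < spec.missing_rate
        table = table.mask(pd.DataFrame(holes, index=table.index,
                                        columns=table.columns))
    return table
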