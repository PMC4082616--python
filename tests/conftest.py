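"""Shared fixtures: small synthetic cohorts with known planted structure."""

from __future__ import annotations

import numpy as np
import pytest

import sparsekm as sk


def trait_cohort(
    n: int,
    p: int,
    frac: float,
    k: int,
    delta: float,
    seed: int,
    joint: bool = True,
    n_sources: int = 1,
):
    """Standardized trait-type matrices with a planted partition and no
    covariate effects -- the workhorse input for clustering properties."""
    sources = [
        sk.SourceSpec(f"s{i + 1}", p, "trait", informative_fraction=frac)
        for i in range(n_sources)
    ]
    spec = sk.CohortSpec(
        n_samples=n,
        sources=sources,
        k_true=k,
        effect_size=delta,
        joint_structure=joint,
        covariate_effects={},
        rin_effect=0.0,
        seed=seed,
    )
    bundles, truth = sk.generate_cohort(spec)
    mats = [sk.standardize_features(b.data) for b in bundles]
    return mats, truth


@pytest.fixture(scope="session")
def two_class_matrix():
    """One strongly structured 2-class matrix plus its truth."""
    (x,), truth = trait_cohort(40, 60, 0.2, 2, 2.5, seed=11)
    return x, truth.partitions["s1"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
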