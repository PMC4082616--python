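"""Partition concordance, weighted PCA, and class-trait association tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

import sparsekm as sk
from sparsekm.characterize import fisher_exact_2xc
from tests.conftest import trait_cohort


def pair_counting_oracle(a, b):
    """Brute-force Rand / adjusted Rand via explicit pair counting."""
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(range(len(a)), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif not sa and not sb:
            n00 += 1
        elif sa:
            n10 += 1
        else:
            n01 += 1
    total = n11 + n00 + n10 + n01
    rand = (n11 + n00) / total
    denom = (n00 + n01) * (n01 + n11) + (n00 + n10) * (n10 + n11)
    ari = 1.0 if denom == 0 else 2.0 * (n00 * n11 - n01 * n10) / denom
    return rand, ari


def all_partitions(n):
    """Every set partition of range(n) as a label vector."""
    if n == 0:
        yield []
        return
    for part in all_partitions(n - 1):
        k = max(part) + 1 if part else 0
        for c in range(k + 1):
            yield part + [c]


class TestComparePartitions:
    def test_identical_two_class_split_is_unit(self):
        labels = np.repeat([1, 2], [27, 13])
        c = sk.compare_partitions(labels, labels.copy())
        assert c.rand == 1.0 and c.adjusted_rand == 1.0
        assert c.n_common_samples == 40

    def test_hand_example(self):
        c = sk.compare_partitions([1, 1, 2, 2], [1, 2, 1, 2])
        assert c.rand == pytest.approx(1 / 3)
        assert c.adjusted_rand == pytest.approx(-0.5)

    def test_label_permutation_invariance(self, rng):
        a = rng.integers(0, 3, 30)
        relabeled = np.array([{0: 7, 1: 2, 2: 5}[v] for v in a])
        c = sk.compare_partitions(a, relabeled)
        assert c.rand == 1.0 and c.adjusted_rand == 1.0

    def test_symmetry(self, rng):
        a, b = rng.integers(0, 3, 25), rng.integers(0, 4, 25)
        cab = sk.compare_partitions(a, b)
        cba = sk.compare_partitions(b, a)
        assert cab.rand == cba.rand
        assert cab.adjusted_rand == pytest.approx(cba.adjusted_rand)

    def test_series_intersected_on_sample_ids(self):
        a = pd.Series([1, 1, 2, 2], index=list("abcd"))
        b = pd.Series([1, 2, 2], index=list("bcd"))
        c = sk.compare_partitions(a, b)
        assert c.n_common_samples == 3

    def test_matches_pair_counting_oracle_exhaustively(self):
        """All partition pairs for n <= 5; seeded samples for n = 6-8."""
        rng = np.random.default_rng(0)
        for n in range(2, 6):
            parts = [np.array(p) for p in all_partitions(n)]
            for a in parts:
                for b in parts:
                    rand, ari = pair_counting_oracle(a, b)
                    c = sk.compare_partitions(a, b)
                    assert c.rand == pytest.approx(rand, abs=1e-12)
                    assert c.adjusted_rand == pytest.approx(ari, abs=1e-12)
        for n in (6, 7, 8):
            for _ in range(100):
                a = rng.integers(0, rng.integers(2, 5), n)
                b = rng.integers(0, rng.integers(2, 5), n)
                rand, ari = pair_counting_oracle(a, b)
                c = sk.compare_partitions(a, b)
                assert c.rand == pytest.approx(rand, abs=1e-12)
                assert c.adjusted_rand == pytest.approx(ari, abs=1e-12)

    def test_fewer_than_two_common_samples_rejected(self):
        with pytest.raises(ValueError):
            sk.compare_partitions(
                pd.Series([1], index=["a"]), pd.Series([1], index=["a"])
            )


class TestWeightedPCA:
    def test_uniform_weights_match_unweighted_pca(self, rng):
        x = rng.normal(0, 1, (20, 6))
        sw, ratio_w = sk.weighted_pca(x, np.full(6, 0.3), 2)
        su, ratio_u = sk.weighted_pca(x, np.ones(6), 2)
        np.testing.assert_allclose(ratio_w, ratio_u, atol=1e-10)
        for j in range(2):  # scores equal up to scale and sign
            r = np.corrcoef(sw.iloc[:, j], su.iloc[:, j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_zero_weights_restrict_subspace(self, rng):
        x = rng.normal(0, 1, (15, 5))
        w = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        scores, ratio = sk.weighted_pca(x, w, 2)
        assert ratio.sum() == pytest.approx(1.0)  # rank-2 weighted matrix

    def test_classes_separate_along_pc1(self, two_class_matrix):
        x, truth = two_class_matrix
        res = sk.SparseKMeans(x).fit(2, 3.0, seed=0)
        scores, ratio = res.weighted_pca(2)
        pc1 = scores["PC1"].to_numpy()
        g1, g2 = pc1[truth == 1], pc1[truth == 2]
        gap = abs(g1.mean() - g2.mean())
        spread = max(g1.std(), g2.std())
        assert gap > 2 * spread
        assert (np.diff(ratio) <= 1e-12).all() and ratio.sum() <= 1 + 1e-9

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            sk.weighted_pca(rng.normal(0, 1, (5, 3)), np.zeros(3))


class TestFisherExact:
    def test_diagonal_3_3_table(self):
        p, flags = fisher_exact_2xc(np.array([[3, 0], [0, 3]]))
        assert p == pytest.approx(0.1)
        assert flags["method"] == "enumeration"

    def test_matches_scipy_on_2x2(self, rng):
        for _ in range(25):
            t = rng.integers(0, 8, (2, 2)) + 1
            p_ours, _ = fisher_exact_2xc(t)
            _, p_scipy = fisher_exact(t)
            assert p_ours == pytest.approx(p_scipy, abs=1e-9)

    def test_2x3_agrees_with_monte_carlo(self, rng):
        t = np.array([[5, 1, 2], [1, 6, 3]])
        p_enum, _ = fisher_exact_2xc(t)
        p_mc, flags = fisher_exact_2xc(t, max_tables=1, seed=0)
        assert flags["method"] == "monte-carlo"
        assert p_mc == pytest.approx(p_enum, abs=4 * flags["se"] + 1e-3)

    def test_variable_identical_to_class_minimum_p(self):
        labels = np.repeat([1, 2], 6)
        res = sk.categorical_class_association(labels, labels, name="copy")
        # the observed table attains the minimum achievable probability
        p_point = 2 / 924  # 2 * 1/C(12,6)
        assert res.p_value == pytest.approx(p_point)

    def test_type_i_error_conservative(self, rng):
        hits = 0
        for _ in range(200):
            labels = rng.integers(0, 2, 20)
            var = rng.choice(["x", "y"], 20)
            if len(set(labels)) < 2 or len(set(var)) < 2:
                continue
            res = sk.categorical_class_association(labels, var, seed=0)
            hits += res.p_value < 0.05
        assert hits / 200 <= 0.05 + 0.02

    def test_missing_excluded_pairwise(self):
        labels = [1, 1, 1, 2, 2, 2]
        var = ["a", "a", None, "b", "b", "b"]
        res = sk.categorical_class_association(labels, var)
        assert res.flags["n_missing"] == 1


class TestContinuousAssociation:
    def test_power_at_two_sd_shift(self, rng):
        hits = 0
        for rep in range(20):
            labels = np.repeat([1, 2], 20)
            vals = rng.normal(0, 1, 40) + 2.0 * (labels == 2)
            res = sk.continuous_class_association(labels, vals)
            hits += res.p_value < 0.01
        assert hits >= 19

    def test_null_p_uniformish(self, rng):
        ps = []
        for _ in range(200):
            labels = np.repeat([1, 2], 10)
            vals = rng.normal(0, 1, 20)
            ps.append(sk.continuous_class_association(labels, vals).p_value)
        ps = np.array(ps)
        assert abs((ps < 0.5).mean() - 0.5) < 0.1
        assert (ps < 0.05).mean() < 0.1

    def test_three_classes_dispatch_anova(self, rng):
        labels = np.repeat([1, 2, 3], 8)
        res = sk.continuous_class_association(labels, rng.normal(0, 1, 24))
        assert res.test == "anova"

    def test_unequal_variance_triggers_welch(self, rng):
        labels = np.repeat([1, 2], 30)
        vals = np.concatenate([rng.normal(0, 0.2, 30), rng.normal(0, 5.0, 30)])
        res = sk.continuous_class_association(labels, vals)
        assert res.test == "t_welch"

    def test_degenerate_zero_variance_flagged(self):
        labels = [1, 1, 2, 2]
        res = sk.continuous_class_association(labels, [3.0, 3.0, 5.0, 5.0])
        assert res.flags.get("zero_within_class_variance")


class TestLogistic:
    @pytest.fixture
    def covariates(self, rng):
        n = 40
        return pd.DataFrame(
            {
                "age_at_mri": rng.uniform(1, 18, n),
                "sex": rng.choice(["M", "F"], n),
                "race": rng.choice(["w", "a"], n),
            }
        )

    def test_null_trait_or_near_one(self, rng, covariates):
        ors = []
        for _ in range(40):
            labels = rng.integers(1, 3, 40)
            while len(set(labels)) < 2:
                labels = rng.integers(1, 3, 40)
            trait = rng.normal(0, 1, 40)
            res = sk.trait_class_logistic(labels, trait, covariates)
            if not res.flags.get("perfect_separation"):
                ors.append(res.effect)
        assert 0.8 < np.median(ors) < 1.25

    def test_planted_log_odds_recovered(self, rng, covariates):
        # at n=40 the slope MLE has SE ~ 0.45, so a tight window around the
        # planted log-OR of 1.0 cannot be hit reliably; check the location
        # of the estimate distribution plus coverage of a 2-SE-wide window
        est = []
        for rep in range(40):
            trait = rng.normal(0, 1, 40)
            prob = 1 / (1 + np.exp(-(0.0 + 1.0 * trait)))
            labels = (rng.uniform(size=40) < prob).astype(int) + 1
            if len(set(labels)) < 2:
                continue
            res = sk.trait_class_logistic(labels, trait, covariates)
            if res.flags.get("perfect_separation"):
                continue
            est.append(np.log(res.effect))
        est = np.asarray(est)
        assert 0.6 <= np.median(est) <= 1.5
        assert ((est >= 0.3) & (est <= 2.0)).mean() >= 0.75

    def test_trait_equal_to_class_flags_separation(self, covariates):
        labels = np.repeat([1, 2], 20)
        res = sk.trait_class_logistic(labels, (labels == 2).astype(float),
                                      covariates)
        assert res.flags.get("perfect_separation")
        assert np.isnan(res.p_value)

    def test_more_than_two_classes_rejected(self, rng, covariates):
        with pytest.raises(ValueError):
            sk.trait_class_logistic(
                np.repeat([1, 2, 3], 14)[:40], rng.normal(0, 1, 40), covariates
            )


def test_association_p_invariant_to_sample_order(rng):
    labels = np.repeat([1, 2], 15)
    vals = rng.normal(0, 1, 30) + 0.8 * (labels == 2)
    cat = rng.choice(["x", "y"], 30)
    perm = rng.permutation(30)
    r1 = sk.continuous_class_association(labels, vals)
    r2 = sk.continuous_class_association(labels[perm], vals[perm])
    assert r1.p_value == pytest.approx(r2.p_value)
    c1 = sk.categorical_class_association(labels, cat, seed=0)
    c2 = sk.categorical_class_association(labels[perm], cat[perm], seed=0)
    assert c1.p_value == pytest.approx(c2.p_value)
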