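"""Integrative sparse k-means: equal-total-SS scaling, the shared-partition
fit, the within-dataset permutation null."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import sparsekm as sk
from sparsekm.bundles import DatasetBundle
from tests.conftest import trait_cohort


def _bundles(mats, names):
    return [DatasetBundle(nm, m) for nm, m in zip(names, mats)]


class TestScaleDatasets:
    def test_hand_example_tss_100_and_400(self):
        a = pd.DataFrame(np.diag([5.0, -5.0, 5.0, -5.0]))  # TSS = 100 - 25 = 75
        # build exact TSS via centered columns instead
        col = np.array([-5.0, 5.0, 0.0, 0.0])
        a = pd.DataFrame({0: col})                        # TSS = 50
        b = pd.DataFrame({0: 2 * col})                    # TSS = 200
        multi = sk.scale_datasets(_bundles([a, b], ["a", "b"]))
        np.testing.assert_allclose(multi.scale_factors, [1.0, 0.5])
        tss = [((m.data - m.data.mean()) ** 2).sum().sum() for m in multi.bundles]
        assert tss[0] == pytest.approx(tss[1])

    def test_identical_datasets_unit_factors(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (8, 4)))
        multi = sk.scale_datasets(_bundles([m, m.copy()], ["a", "b"]))
        np.testing.assert_allclose(multi.scale_factors, [1.0, 1.0])

    def test_equal_tss_postcondition(self, rng):
        mats = [pd.DataFrame(rng.normal(0, s, (10, p)))
                for s, p in ((1, 5), (4, 50), (0.3, 2))]
        multi = sk.scale_datasets(_bundles(mats, ["a", "b", "c"]))
        tss = np.array([
            ((m.data - m.data.mean()) ** 2).sum().sum() for m in multi.bundles
        ])
        assert tss.max() / tss.min() == pytest.approx(1.0, abs=1e-8)

    def test_zero_tss_fatal(self):
        a = pd.DataFrame(np.ones((4, 2)))
        b = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError, match="zero total"):
            sk.scale_datasets(_bundles([a, b], ["a", "b"]))

    def test_mismatched_samples_fatal(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, (5, 2)), index=list("abcde"))
        b = pd.DataFrame(rng.normal(0, 1, (5, 2)), index=list("abcdX"))
        with pytest.raises(ValueError, match="sample ids"):
            sk.scale_datasets(_bundles([a, b], ["a", "b"]))


class TestFitIntegrative:
    def test_shared_partition_recovered_noise_source_downweighted(self):
        mats, truth = trait_cohort(50, 80, 0.15, 2, 2.5, seed=61,
                                   joint=True, n_sources=2)
        noise = pd.DataFrame(
            np.random.default_rng(99).normal(0, 1, (50, 80)),
            index=mats[0].index,
        )
        noise = sk.standardize_features(noise)
        model = sk.IntegrativeSparseKMeans(
            _bundles([*mats, noise], ["a", "b", "noise"])
        )
        res = model.fit(2, 0.4, seed=3)
        assert adjusted_rand_score(res.labels, truth.partitions["s1"]) >= 0.9
        # at the L1 bound every dataset's weight sum equals s_d, so compare
        # each source's contribution to the joint objective instead
        shares = {
            nm: float(res.weights[nm] @ res.bcss[nm]) for nm in res.weights
        }
        assert shares["noise"] == min(shares.values())

    def test_t_equal_one_no_sparsity_matches_standard_kmeans(self):
        mats, _ = trait_cohort(30, 40, 0.3, 2, 3.0, seed=62, n_sources=2)
        model = sk.IntegrativeSparseKMeans(_bundles(mats, ["a", "b"]))
        res = model.fit(2, 1.0, seed=4)
        for nm in res.weights:
            assert (res.weights[nm] > 0).all()
        concat = np.hstack([b.values() for b in model.multi.bundles])
        std = sk.standard_kmeans(concat, 2, seed=4)
        assert adjusted_rand_score(res.labels, std) == 1.0

    def test_single_dataset_equals_sparse_kmeans_same_seed(self):
        (x,), _ = trait_cohort(30, 36, 0.2, 2, 2.0, seed=63)
        t = 0.5
        s = 1 + t * (np.sqrt(36) - 1)
        multi_res = sk.IntegrativeSparseKMeans(_bundles([x], ["a"])).fit(
            2, t, seed=7
        )
        single_res = sk.SparseKMeans(x).fit(2, s, seed=7)
        assert (multi_res.labels.to_numpy() == single_res.labels.to_numpy()).all()
        np.testing.assert_allclose(
            multi_res.weights["a"].to_numpy(),
            single_res.weights.to_numpy(),
            atol=1e-10,
        )
        assert multi_res.objective == pytest.approx(single_res.objective)

    def test_input_scaling_invariance(self):
        mats, _ = trait_cohort(30, 30, 0.2, 2, 2.5, seed=64, n_sources=2)
        res = sk.IntegrativeSparseKMeans(_bundles(mats, ["a", "b"])).fit(
            2, 0.5, seed=8
        )
        res_scaled = sk.IntegrativeSparseKMeans(
            _bundles([mats[0] * 7.0, mats[1]], ["a", "b"])
        ).fit(2, 0.5, seed=8)
        assert adjusted_rand_score(res.labels, res_scaled.labels) == 1.0

    def test_t_out_of_range_rejected(self):
        mats, _ = trait_cohort(20, 10, 0.2, 2, 2.0, seed=65, n_sources=2)
        model = sk.IntegrativeSparseKMeans(_bundles(mats, ["a", "b"]))
        for t in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                model.fit(2, t, seed=0)

    def test_per_dataset_report_identities(self):
        mats, _ = trait_cohort(30, 24, 0.3, 2, 2.5, seed=66, n_sources=3)
        res = sk.IntegrativeSparseKMeans(
            _bundles(mats, ["dura", "blood", "cranial"])
        ).fit(2, 0.3, seed=9)
        for nm, w in res.weights.items():
            assert res.pct_nonzero_weights(nm) == pytest.approx(
                100.0 * (w > 0).sum() / len(w)
            )
            assert np.isclose(np.linalg.norm(w), 1.0, atol=1e-8) or not (w > 0).any()
            assert w.sum() <= res.s_bounds[nm] + 1e-8
        assert "Integrative" in res.summary()


class TestPermuteWithinDatasets:
    def test_single_dataset_warns_vacuous(self):
        (x,), _ = trait_cohort(10, 6, 0.3, 2, 2.0, seed=71)
        multi = sk.scale_datasets(_bundles([x], ["a"]))
        with pytest.warns(UserWarning, match="vacuous"):
            sk.permute_within_datasets(multi, seed=0)

    def test_internal_structure_preserved_rows_intact(self):
        mats, _ = trait_cohort(20, 8, 0.4, 2, 2.0, seed=72, n_sources=2)
        multi = sk.scale_datasets(_bundles(mats, ["a", "b"]))
        null = sk.permute_within_datasets(multi, seed=1)
        for before, after in zip(multi.bundles, null.bundles):
            corr_b = np.corrcoef(before.values().T)
            corr_a = np.corrcoef(after.values().T)
            np.testing.assert_allclose(corr_a, corr_b, atol=1e-10)
            # rows are moved intact: sorted row multiset unchanged
            rb = np.sort(before.values(), axis=0)
            ra = np.sort(after.values(), axis=0)
            np.testing.assert_allclose(np.sort(rb, axis=0), np.sort(ra, axis=0))

    def test_alignment_destroyed_between_datasets(self):
        mats, _ = trait_cohort(40, 60, 0.3, 2, 3.0, seed=73, joint=True,
                               n_sources=2)
        multi = sk.scale_datasets(_bundles(mats, ["a", "b"]))
        aris = []
        for s in range(10):
            null = sk.permute_within_datasets(multi, seed=s)
            la = sk.SparseKMeans(null.bundles[0].data).fit(2, 4.0, seed=s).labels
            lb = sk.SparseKMeans(null.bundles[1].data).fit(2, 4.0, seed=s).labels
            aris.append(adjusted_rand_score(la, lb))
        assert abs(np.mean(aris)) < 0.15


class TestIntegrativeGap:
    def test_observed_equal_to_null_gives_zero_gap(self):
        inf = sk.gap_inference(0.0, 0.1)
        assert inf.gap == 0.0

    def test_shared_structure_significant(self):
        mats, _ = trait_cohort(40, 60, 0.15, 2, 2.5, seed=81, joint=True,
                               n_sources=2)
        model = sk.IntegrativeSparseKMeans(_bundles(mats, ["a", "b"]))
        inf, info = sk.integrative_gap(model, 2, 0.5, n_permutations=15,
                                       n_starts=10, seed=0)
        assert inf.gap > 0 and inf.p_value < 0.05
        assert info["objective"] > 0

    def test_independent_structure_not_significant(self):
        mats, _ = trait_cohort(40, 60, 0.15, 2, 2.5, seed=82, joint=False,
                               n_sources=2)
        model = sk.IntegrativeSparseKMeans(_bundles(mats, ["a", "b"]))
        inf, _ = sk.integrative_gap(model, 2, 0.5, n_permutations=15,
                                    n_starts=10, seed=1)
        assert inf.ci95[0] <= 0 <= inf.ci95[1]

    def test_grid_search_selects_two_classes_on_shared_structure(self):
        mats, truth = trait_cohort(36, 30, 0.25, 2, 2.5, seed=83, joint=True,
                                   n_sources=2)
        search = sk.IntegrativeSparseKMeans(_bundles(mats, ["a", "b"])).select(
            k_range=(2, 3), n_tuning=4, n_permutations=6, n_starts=8, seed=2
        )
        assert search.best_k == 2
        assert adjusted_rand_score(
            search.results.labels, truth.partitions["s1"]
        ) >= 0.9
        assert "Integrative" in search.summary()
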