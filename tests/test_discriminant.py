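"""Univariate bin tests, BY/BH adjustment and the top-n shortlist."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from iknife import SyntheticConfig, generate_cohort, build_feature_matrix
from iknife.discriminant import adjust_by, log2_fold_change, top_discriminant
from iknife.discriminant import test_bins as run_bin_tests


class TestAdjustBY:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_by([0.01]), [0.01])

    def test_hand_computed_example(self):
        """m=4, c(4)=25/12; step-up on (0.001, 0.01, 0.02, 0.04)."""
        q = adjust_by([0.001, 0.01, 0.02, 0.04])
        np.testing.assert_allclose(
            q, [4 * 25 / 12 * 0.001, 4 * 25 / 12 * 0.01 / 2,
                4 * 25 / 12 * 0.02 / 3, 4 * 25 / 12 * 0.04 / 4], rtol=1e-12)

    def test_matches_naive_stepup_loop_and_statsmodels(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200) ** 2
        q = adjust_by(p)
        # naive loop oracle
        m = p.size
        c = sum(1.0 / k for k in range(1, m + 1))
        order = np.argsort(p)
        naive = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [m * c * p[order[j]] / (j + 1)
                          for j in range(rank_pos, m)]
            naive[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, naive, rtol=1e-12)
        from statsmodels.stats.multitest import multipletests
        _, q_sm, _, _ = multipletests(p, method="fdr_by")
        np.testing.assert_allclose(q, q_sm, rtol=1e-10)

    def test_by_dominates_bh_and_is_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=150)
        q_by = adjust_by(p, "by")
        q_bh = adjust_by(p, "bh")
        assert np.all(q_by >= q_bh - 1e-15)
        assert np.all(q_by >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q_by[order]) >= -1e-15)
        from statsmodels.stats.multitest import multipletests
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q_bh, q_sm, rtol=1e-10)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_by([0.5, 1.2])


class TestRankTests:
    def test_ranksum_approximation_close_to_exact_permutation(self):
        """2 vs 4 toy data: normal approximation vs full enumeration."""
        a = np.array([5.0, 7.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        observed = ranks[:2].sum()
        # exact two-sided permutation distribution of the rank-sum statistic
        stats = [sum(sorted(rankdata(pooled)[list(idx)]))
                 for idx in itertools.combinations(range(6), 2)]
        mean = np.mean(stats)
        exact_p = np.mean([abs(s - mean) >= abs(observed - mean) - 1e-9 for s in stats])
        from scipy.stats import mannwhitneyu
        approx_p = mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False).pvalue
        assert approx_p == pytest.approx(exact_p, abs=0.07)

    def test_null_cohort_has_uniformish_p_and_small_fold_changes(self):
        cfg = SyntheticConfig(seed=21, classes=("a", "b"), patients_per_class=8,
                              cancer_class=None,
                              templates=SyntheticConfig(seed=0).templates)
        # identical class distributions: no fold changes anywhere
        for t in cfg.templates:
            t.class_fold_change.clear()
        matrix = build_feature_matrix(generate_cohort(cfg))
        results = run_bin_tests(matrix, ["a", "b"], level="sample")
        informative = results.loc[results["pooled_median_intensity"] > 0]
        assert informative["P"].min() > 1e-4  # nothing wildly significant
        assert (results["q"] < 0.01).sum() == 0
        assert informative["log2_fold_change"].abs().median() < 0.5

    def test_planted_bin_detected_with_small_q_and_positive_fc(self, default_matrix):
        results = run_bin_tests(default_matrix, ["ovarian_cancer", "normal"])
        planted = results.loc[np.isclose(results["bin"], 699.4)].iloc[0]
        assert planted["q"] < 1e-3
        # TIC normalisation attenuates the raw fold 4, but the sign and a
        # substantial effect toward the cancer class must survive
        assert planted["log2_fold_change"] > 0.5
        assert planted["q"] <= results["q"].quantile(0.01)

    def test_constant_bins_get_p_one(self, noiseless_cohort):
        """Bins identical across every unit (here: all-zero) get P = 1."""
        matrix = build_feature_matrix(noiseless_cohort)
        results = run_bin_tests(matrix, ["ovarian_cancer", "normal"])
        empty = np.all(matrix.values() == 0, axis=0)
        assert empty.sum() > 3000
        assert (results.loc[empty, "P"] == 1.0).all()

    def test_three_classes_use_kruskal_wallis(self, default_matrix):
        results = run_bin_tests(default_matrix,
                            ["ovarian_cancer", "borderline", "normal"])
        assert (results["test"] == "kruskal-wallis").all()
        assert results.loc[np.isclose(results["bin"], 673.4), "q"].iloc[0] < 1e-3

    def test_scaling_one_unit_does_not_change_p(self, small_cohort):
        """Rank tests + TIC normalisation are scale-invariant per spectrum."""
        from iknife import CohortTable
        scaled_records = [
            r.replace_peaks(r.mz, r.intensity * (50.0 if i == 0 else 1.0))
            for i, r in enumerate(small_cohort)
        ]
        m1 = build_feature_matrix(small_cohort)
        m2 = build_feature_matrix(CohortTable(records=scaled_records))
        r1 = run_bin_tests(m1, ["ovarian_cancer", "normal"])
        r2 = run_bin_tests(m2, ["ovarian_cancer", "normal"])
        np.testing.assert_allclose(r1["P"], r2["P"], atol=1e-9)

    def test_too_few_units_rejected(self, default_matrix):
        with pytest.raises(ValueError, match="fewer than 3"):
            run_bin_tests(_subset(default_matrix, max_samples=2), ["ovarian_cancer", "normal"])


def _subset(matrix, max_samples):
    import pandas as pd
    meta = matrix.metadata
    keep = []
    for cls, grp in meta.groupby("tissue_class"):
        samples = grp[["patient_id", "sample_id"]].drop_duplicates().head(max_samples)
        mask = pd.Series(list(zip(meta["patient_id"], meta["sample_id"]))).isin(
            list(map(tuple, samples.to_numpy()))).to_numpy()
        keep.append(mask)
    mask = np.logical_or.reduce(keep)
    from iknife.preprocess import FeatureMatrix
    return FeatureMatrix(intensities=matrix.intensities.loc[mask],
                         metadata=meta.loc[mask], grid=matrix.grid)


class TestFoldChange:
    def test_antisymmetric(self, default_matrix):
        ab = log2_fold_change(default_matrix, 699.4, "ovarian_cancer", "normal")
        ba = log2_fold_change(default_matrix, 699.4, "normal", "ovarian_cancer")
        assert ab == pytest.approx(-ba, abs=1e-12)

    def test_equal_medians_give_zero(self, default_matrix):
        assert log2_fold_change(default_matrix, 650.0, "borderline", "normal") == \
            pytest.approx(0.0, abs=0.6)


class TestTopDiscriminant:
    def test_planted_bins_lead_the_shortlist(self, default_matrix):
        results = run_bin_tests(default_matrix, ["ovarian_cancer", "normal"])
        top = top_discriminant(results, n=5)
        assert sorted(np.round(top["bin"], 1)) == [673.4, 685.5, 699.4, 742.5, 744.5]
        assert (top["q"] < 0.001).all()

    def test_default_n_is_ten(self, default_matrix):
        results = run_bin_tests(default_matrix, ["ovarian_cancer", "normal"])
        assert len(top_discriminant(results)) <= 10

    def test_empty_result_warns(self, default_matrix):
        results = run_bin_tests(default_matrix, ["borderline", "normal"])
        impossible = results.assign(P=1.0, q=1.0)
        with pytest.warns(UserWarning, match="0 bins"):
            out = top_discriminant(impossible, n=10)
        assert len(out) == 0
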