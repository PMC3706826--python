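"""Expression processing and the error-weighted differential-expression
stage: normalisation, weighted ANOVA, FDR, fold changes, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bivalscore as bv
from bivalscore.expression import _ewanova_matrix


def _matrix(values, ses=None, groups=None):
    values = pd.DataFrame(values)
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    values.index = [f"p{i}" for i in range(values.shape[0])]
    if ses is None:
        ses = pd.DataFrame(np.ones_like(values, dtype=float),
                           index=values.index, columns=values.columns)
    else:
        ses = pd.DataFrame(ses, index=values.index, columns=values.columns)
    if groups is None:
        groups = pd.Series(["a"] * values.shape[1], index=values.columns)
    else:
        groups = pd.Series(groups, index=values.columns)
    return bv.ExpressionMatrix(values.astype(float), ses.astype(float), groups)


class TestQuantileNormalize:
    def test_two_by_two_hand_calculation(self):
        em = _matrix([[1.0, 2.0], [3.0, 8.0]])
        out = bv.quantile_normalize(em).intensities
        np.testing.assert_allclose(out.to_numpy(),
                                   [[1.5, 1.5], [5.5, 5.5]])

    def test_single_column_unchanged(self):
        em = _matrix([[3.0], [1.0], [7.0]])
        out = bv.quantile_normalize(em).intensities
        np.testing.assert_allclose(out.to_numpy(), em.intensities.to_numpy())

    def test_columns_share_sorted_vector(self):
        rng = np.random.default_rng(2)
        em = _matrix(rng.lognormal(4, 1, size=(50, 6)))
        out = bv.quantile_normalize(em).intensities.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        em = _matrix(rng.lognormal(4, 1, size=(40, 5)))
        once = bv.quantile_normalize(em)
        twice = bv.quantile_normalize(once)
        np.testing.assert_allclose(twice.intensities.to_numpy(),
                                   once.intensities.to_numpy(), atol=1e-12)

    def test_ties_share_rank_mean(self):
        em = _matrix([[2.0, 1.0], [2.0, 5.0], [4.0, 9.0]])
        out = bv.quantile_normalize(em).intensities.to_numpy()
        # tied values in column 0 get the mean of the rank-1/rank-2 targets
        assert out[0, 0] == out[1, 0]

    def test_rejects_missing_values(self):
        em = _matrix([[1.0, 2.0], [3.0, 8.0]])
        em.intensities.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            bv.quantile_normalize(em)


class TestBackgroundSubtract:
    def test_subtracts_control_mean(self):
        em = _matrix([[250.0, 300.0], [100.0, 100.0]])
        out = bv.background_subtract(em, ["p1"])
        assert out.intensities.loc["p0", "s0"] == 150.0

    def test_floors_at_small_constant(self):
        em = _matrix([[50.0, 50.0], [100.0, 100.0]])
        out = bv.background_subtract(em, ["p1"])
        assert out.intensities.loc["p0", "s0"] == 1.0

    def test_zero_controls_leave_matrix_unchanged(self):
        em = _matrix([[0.5, 250.0], [0.0, 0.0]])
        out = bv.background_subtract(em, ["p1"])
        np.testing.assert_allclose(out.intensities.to_numpy(),
                                   em.intensities.to_numpy())

    def test_empty_control_list_rejected(self):
        em = _matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            bv.background_subtract(em, [])


class TestErrorWeightedAnova:
    def test_constant_values_give_f_zero_p_one(self):
        F, p = bv.error_weighted_anova([10.0] * 6, [1.0] * 6,
                                       ["a"] * 3 + ["b"] * 3)
        assert F == 0.0 and p == 1.0

    def test_equal_ses_reduce_to_ordinary_anova(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            vals = rng.normal(size=9)
            groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
            F, p = bv.error_weighted_anova(vals, [2.5] * 9, groups)
            F0, p0 = stats.f_oneway(vals[:3], vals[3:6], vals[6:])
            assert F == pytest.approx(F0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_zero_within_variability_flags_not_crashes(self):
        F, p = bv.error_weighted_anova([1.0, 1.0, 2.0, 2.0], [1.0] * 4,
                                       ["a", "a", "b", "b"])
        assert np.isinf(F) and p == 0.0

    def test_null_pvalues_uniform(self):
        """With correctly specified heteroscedastic weights the F statistic
        is exactly F-distributed, so null p-values are uniform."""
        rng = np.random.default_rng(21)
        n_probes, groups = 2000, ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        codes = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        ses = 0.5 + rng.chisquare(3, size=(n_probes, 9)) / 3
        values = 10 + rng.normal(size=(n_probes, 9)) * ses
        _, p = _ewanova_matrix(values, ses, codes, 3)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_rejects_single_group_and_bad_ses(self):
        with pytest.raises(ValueError):
            bv.error_weighted_anova([1, 2, 3], [1, 1, 1], ["a", "a", "a"])
        with pytest.raises(ValueError):
            bv.error_weighted_anova([1, 2], [1, 0], ["a", "b"])


class TestBhFdr:
    def test_single_pvalue_unchanged(self):
        assert bv.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bv.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_step_up_hand_computation(self):
        got = bv.bh_fdr([0.01, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.8 / 15, 0.8], rtol=1e-12)

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        direct = bv.bh_fdr(p)
        via_perm = np.empty(50)
        via_perm[perm] = bv.bh_fdr(p[perm])
        np.testing.assert_allclose(via_perm, direct)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bv.bh_fdr([])


class TestFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (10.0, 20.0, 2.0),
        (10.0, 5.0, -2.0),
        (7.0, 7.0, 1.0),
    ])
    def test_signed_ratio_convention(self, a, b, expected):
        assert bv.fold_change(a, b) == pytest.approx(expected)

    def test_antisymmetric(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.uniform(1, 100, 2)
            fa, fb = bv.fold_change(a, b), bv.fold_change(b, a)
            if abs(fa) > 1:
                assert fa == pytest.approx(-fb)

    def test_rejects_nonpositive_means(self):
        with pytest.raises(ValueError):
            bv.fold_change(0.0, 5.0)


class TestPairwiseDe:
    def test_planted_truth_recovery(self):
        em, truth = bv.simulate_expression(2000, n_de=200, lfc=1.0,
                                           se_scale=0.05, seed=14)
        de = bv.pairwise_de(em, contrasts=(("day0", "day2"),))
        sig = de[de["significant"]]
        tp = sig["probe_id"].isin(truth[truth].index).sum()
        sensitivity = tp / truth.sum()
        empirical_fdr = 1 - tp / max(len(sig), 1)
        assert sensitivity >= 0.8
        assert empirical_fdr <= 0.08
        # fold-change direction matches the planted up-shift in day2
        recovered = sig[sig["probe_id"].isin(truth[truth].index)]
        assert (recovered["fold_change"] > 0).all()

    def test_null_significant_count_bounded(self):
        em, _ = bv.simulate_expression(2000, n_de=0, seed=15)
        de = bv.pairwise_de(em, contrasts=(("day0", "day2"),))
        # E[#significant] <= alpha * m under BH; allow generous slack
        assert de["significant"].sum() <= 0.05 * 2000

    def test_small_group_rejected(self):
        em, _ = bv.simulate_expression(
            20, design=("day0", "day0", "day2", "day2", "day4", "day4"),
            seed=1)
        em.groups["day0_2"] = "solo"
        with pytest.raises(ValueError):
            bv.pairwise_de(em, contrasts=(("solo", "day2"),))


class TestTimepointSpecificSet:
    def _results(self):
        rows = []
        for probe, sigs in [("p1", {"day2:day0"}),
                            ("p2", {"day2:day0", "day10:day0"}),
                            ("p3", {"day4:day0"})]:
            for c in ("day2:day0", "day4:day0", "day10:day0"):
                rows.append({"probe_id": probe, "contrast": c,
                             "significant": c in sigs})
        return pd.DataFrame(rows)

    def test_specific_mode_excludes_shared_hits(self):
        got = bv.timepoint_specific_set(self._results())
        assert got == {"p1"}

    def test_intersection_and_union_modes(self):
        res = self._results()
        assert bv.timepoint_specific_set(res, mode="intersection") == set()
        assert bv.timepoint_specific_set(res, mode="union") == {"p1", "p2", "p3"}

    def test_missing_focal_contrast_rejected(self):
        with pytest.raises(ValueError):
            bv.timepoint_specific_set(self._results(), focal="day7:day0")


class TestPcaScores:
    def test_duplicated_sample_gets_identical_scores(self):
        rng = np.random.default_rng(7)
        X = rng.lognormal(4, 1, size=(30, 4))
        X[:, 3] = X[:, 2]
        em = _matrix(X, groups=["a", "a", "b", "b"])
        scores, _ = bv.pca_scores(em, n_components=2)
        np.testing.assert_allclose(scores.loc["s2", ["PC1", "PC2"]].astype(float),
                                   scores.loc["s3", ["PC1", "PC2"]].astype(float),
                                   atol=1e-8)

    def test_variance_explained_sums_below_one(self):
        em, _ = bv.simulate_expression(100, seed=5)
        _, var = bv.pca_scores(em, n_components=3)
        assert 0 < var.sum() <= 1.0 + 1e-12

    def test_separated_groups_split_on_pc1(self):
        """A strong planted group shift dominates PC1, mirroring the
        mature-EC versus stem-cell separation seen in practice."""
        rng = np.random.default_rng(9)
        X = rng.normal(100, 1, size=(50, 6))
        X[:, 3:] += 50  # second group strongly shifted
        em = _matrix(X, groups=["a"] * 3 + ["b"] * 3)
        scores, _ = bv.pca_scores(em, n_components=2)
        signs = np.sign(scores["PC1"].to_numpy(dtype=float))
        assert set(signs[:3]) != set(signs[3:])
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1

    def test_too_many_components_rejected(self):
        em, _ = bv.simulate_expression(30, seed=5)
        with pytest.raises(ValueError):
            bv.pca_scores(em, n_components=30)


class TestMatrixIo:
    def test_tsv_round_trip(self, tmp_path):
        em, _ = bv.simulate_expression(20, n_de=2, seed=6)
        path = tmp_path / "expr.tsv"
        em.to_tsv(path)
        back = bv.ExpressionMatrix.from_tsv(path, em.groups)
        pd.testing.assert_frame_equal(back.intensities, em.intensities)
        pd.testing.assert_frame_equal(back.ses, em.ses)
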