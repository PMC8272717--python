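import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relmap.reliability import (
    count_voxels_above,
    icc_3_1,
    icc_3_1_matrix,
    impute_covariates,
    reliability_category,
    roi_summary,
    semipartial_reliability,
    tukey_hinges,
    voxelwise_icc,
    windsorize_tukey,
)


def icc_oracle(data):
    """Explicit two-way ANOVA sum-of-squares computation."""
    x = np.asarray(data, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestWindsorize:
    def test_hand_computed_fences(self):
        out = windsorize_tukey(np.array([1.0, 2, 3, 4, 100]))
        np.testing.assert_array_equal(out, [1, 2, 3, 4, 7])
        assert tukey_hinges([1, 2, 3, 4, 100]) == (2.0, 4.0)

    def test_all_equal_unchanged(self):
        x = np.full(6, 2.5)
        np.testing.assert_array_equal(windsorize_tukey(x), x)

    def test_within_fences_unchanged(self, rng):
        x = np.sort(rng.uniform(0, 1, 20))
        np.testing.assert_array_equal(windsorize_tukey(x), x)

    def test_small_sample_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            out = windsorize_tukey(np.array([1.0, 2.0, 50.0]))
        np.testing.assert_array_equal(out, [1, 2, 50])

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40).map(np.array)
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_range_nonincreasing(self, x):
        once = windsorize_tukey(x)
        assert once.max() - once.min() <= x.max() - x.min() + 1e-9
        np.testing.assert_array_equal(windsorize_tukey(once), once)


class TestICC:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            ([(1, 2), (3, 4), (5, 6)], 1.0),
            ([(1, 2), (2, 1), (1, 2), (2, 1)], -1.0),
            ([(1, 2), (4, 3), (7, 8), (10, 9)], 26 / (26 + 4 / 3)),
        ],
    )
    def test_hand_values(self, rows, expected):
        icc, dec = icc_3_1(np.array(rows, float))
        assert icc == pytest.approx(expected, abs=1e-12)
        assert dec.df_rows == len(rows) - 1

    def test_matches_anova_oracle_on_random_matrices(self, rng):
        for _ in range(1000):
            n = rng.integers(3, 21)
            x = rng.standard_normal((n, 2))
            icc, _ = icc_3_1(x)
            assert icc == pytest.approx(icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc3(self, rng):
        # independent library route as a second oracle
        pingouin = pytest.importorskip("pingouin")
        for _ in range(20):
            n = int(rng.integers(4, 15))
            x = rng.standard_normal((n, 2))
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), 2),
                    "raters": np.tile([0, 1], n),
                    "scores": x.ravel(),
                }
            )
            ref = pingouin.intraclass_corr(df, "targets", "raters", "scores")
            # ICC(C,1) is the two-way mixed consistency single-measure form
            ref_icc = float(ref.set_index("Type").loc["ICC(C,1)", "ICC"])
            assert icc_3_1(x)[0] == pytest.approx(ref_icc, abs=1e-8)

    def test_session_offset_invariance(self, rng):
        x = rng.standard_normal((10, 2))
        shifted = x + np.array([0.0, 5.0])
        assert icc_3_1(shifted)[0] == pytest.approx(icc_3_1(x)[0], abs=1e-10)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal((12, 2))
        assert icc_3_1(3.0 * x - 7.0)[0] == pytest.approx(icc_3_1(x)[0], abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="missing"):
            icc_3_1(np.array([[1.0, np.nan], [2, 3], [4, 5]]))
        with pytest.raises(ValueError, match="constant"):
            icc_3_1(np.ones((5, 2)))
        with pytest.raises(ValueError, match="3 subjects"):
            icc_3_1(np.array([[1.0, 2], [3, 4]]))

    def test_vectorized_matches_scalar(self, rng):
        stack = rng.standard_normal((50, 8, 2))
        vec = icc_3_1_matrix(stack)
        for v in range(50):
            assert vec[v] == pytest.approx(icc_3_1(stack[v])[0], abs=1e-12)


class TestVoxelwiseICC:
    def test_identical_sessions_give_one(self, rng):
        vals = rng.standard_normal((10, 1, 4, 4, 2))
        vals = np.concatenate([vals, vals], axis=1)
        m = voxelwise_icc(vals, windsorize=False)
        np.testing.assert_allclose(m.values(), 1.0, atol=1e-10)

    def test_shuffled_sessions_give_zero_mean(self, rng):
        n, V = 50, 200
        s1 = rng.standard_normal((n, V))
        s2 = s1[rng.permutation(n)]
        vals = np.stack([s1, s2], axis=1)
        m = voxelwise_icc(vals, windsorize=False)
        assert abs(np.mean(m.values())) < 0.1

    def test_missing_subjects_dropped_listwise(self, rng):
        vals = rng.standard_normal((8, 2, 5))
        vals[0, 1, 2] = np.nan
        m = voxelwise_icc(vals, windsorize=False)
        assert m.dropped_counts.ravel()[2] == 1
        assert np.isfinite(m.icc.ravel()[2])

    def test_too_few_subjects_yields_nan(self, rng):
        vals = rng.standard_normal((4, 2, 3))
        vals[:2, 0, 1] = np.nan
        m = voxelwise_icc(vals, windsorize=False)
        assert np.isnan(m.icc.ravel()[1])


class TestROISummary:
    def test_direct_arithmetic(self):
        icc = np.array([0.1, 0.5, 0.9])
        s = roi_summary(icc, np.ones(3, bool), thresholds=(0.4, 0.6))
        assert s.mean == pytest.approx(0.5)
        assert s.median == pytest.approx(0.5)
        assert s.counts_above == {0.4: 2, 0.6: 1}

    def test_single_voxel(self):
        s = roi_summary(np.array([0.3]), np.ones(1, bool))
        assert s.mean == s.median == pytest.approx(0.3)
        assert s.sd == 0.0

    def test_nan_excluded(self):
        icc = np.array([0.2, np.nan, 0.6])
        s = roi_summary(icc, np.ones(3, bool))
        assert s.n_voxels == 2
        assert s.mean == pytest.approx(0.4)

    def test_counts_monotone(self, rng):
        icc = rng.uniform(-0.5, 1.0, 100)
        s = roi_summary(icc, np.ones(100, bool))
        counts = [s.counts_above[t] for t in sorted(s.counts_above)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            roi_summary(np.array([0.1]), np.zeros(1, bool))


def test_reliability_categories():
    assert reliability_category(0.39) == "poor"
    assert reliability_category(0.4) == "fair"
    assert reliability_category(0.6) == "good"
    assert reliability_category(0.74) == "good"
    assert reliability_category(0.75) == "excellent"


class TestImputation:
    def test_no_missing_unchanged(self, rng):
        df = pd.DataFrame(rng.standard_normal((10, 3)), columns=list("abc"))
        out, flags = impute_covariates(df)
        pd.testing.assert_frame_equal(out, df)
        assert not flags.to_numpy().any()

    def test_exact_linear_relation(self):
        x = np.arange(1.0, 9.0)
        y = 2.0 * x
        y[2] = np.nan  # x = 3 there
        out, flags = impute_covariates(pd.DataFrame({"x": x, "y": y}))
        assert out.loc[2, "y"] == pytest.approx(6.0)
        assert flags.loc[2, "y"]

    def test_mar_rmse_below_sd(self, rng):
        n = 200
        z = rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "a": z + 0.3 * rng.standard_normal(n),
                "b": z + 0.3 * rng.standard_normal(n),
                "c": z + 0.3 * rng.standard_normal(n),
            }
        )
        truth = df.copy()
        miss = rng.random((n, 3)) < 0.1
        miss[miss.all(axis=1), 0] = False  # keep one observed per subject
        df = df.mask(pd.DataFrame(miss, columns=df.columns))
        out, flags = impute_covariates(df)
        err = (out - truth)[flags.to_numpy() & out.notna()].stack()
        assert np.sqrt((err**2).mean()) < truth.stack().std()

    def test_mostly_missing_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan, np.nan, np.nan], "b": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="50%"):
            impute_covariates(df)


class TestSemipartial:
    def test_reduces_to_pearson_without_covariates(self, rng):
        for _ in range(100):
            pre = rng.standard_normal(30)
            post = 0.5 * pre + rng.standard_normal(30)
            res = semipartial_reliability(pre, post)
            r = np.corrcoef(pre, post)[0, 1]
            assert res.sr == pytest.approx(r, abs=1e-12)

    def test_post_equal_to_covariate_gives_zero_sr(self, rng):
        cov = rng.standard_normal(50)
        pre = rng.standard_normal(50)
        res = semipartial_reliability(pre, cov.copy(), cov[:, None])
        assert abs(res.sr) < 1e-6

    def test_matches_analytic_semipartial(self, rng):
        # post = 0.5 pre + 1.0 cov + e, all unit normal:
        # sr = 0.5 / sqrt(0.25 + 1 + 1)
        target = 0.5 / np.sqrt(2.25)
        srs = []
        for _ in range(25):
            pre = rng.standard_normal(200)
            cov = rng.standard_normal(200)
            post = 0.5 * pre + 1.0 * cov + rng.standard_normal(200)
            srs.append(semipartial_reliability(pre, post, cov[:, None]).sr)
        assert np.mean(srs) == pytest.approx(target, abs=0.04)

    def test_collinear_covariates_pruned_with_warning(self, rng):
        pre = rng.standard_normal(40)
        post = pre + rng.standard_normal(40)
        cov = rng.standard_normal(40)
        with pytest.warns(UserWarning, match="collinear"):
            res = semipartial_reliability(pre, post, np.column_stack([cov, 2 * cov]))
        assert np.isfinite(res.sr)

    def test_aic_favors_true_model(self, rng):
        pre = rng.standard_normal(100)
        cov = rng.standard_normal(100)
        post = 0.8 * pre + 1.5 * cov + 0.5 * rng.standard_normal(100)
        with_cov = semipartial_reliability(pre, post, cov[:, None])
        without = semipartial_reliability(pre, post)
        assert with_cov.aic < without.aic

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            semipartial_reliability(np.arange(3.0), np.arange(3.0))


class TestThresholdCounts:
    def test_uniform_map(self):
        icc = np.full((4, 4, 4), 0.65)
        table = count_voxels_above(icc, thresholds=(0.4, 0.6, 0.7))
        assert list(table["n_voxels"]) == [64, 64, 0]

    def test_cluster_rule_suppresses_small_blob(self):
        icc = np.zeros((6, 6, 6))
        icc[:2, :5, 0] = 0.8  # 10-voxel blob
        table = count_voxels_above(
            icc, thresholds=(0.7,), min_cluster_sizes={0.7: 12}
        )
        assert table.loc[0, "n_voxels"] == 0

    def test_monotone_in_threshold(self, rng):
        icc = rng.uniform(0, 1, (5, 5, 5))
        table = count_voxels_above(icc, thresholds=(0.2, 0.4, 0.6, 0.8))
        counts = list(table["n_voxels"])
        assert counts == sorted(counts, reverse=True)
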