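"""Voxel-wise GLM contrasts and score regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtconj import (
    CompartmentMap, NoiseSpec, ScoreLinkSpec, Volume,
    build_design, contrast_vector, extract_roi_fit, fit_glm,
    simulate_cohort, voxelwise_regression,
)
from conftest import maps_from_store, pooled_two_sample_t


def random_maps(rng, n_subjects, shape=(5, 5, 5), loc=40.0, scale=3.0):
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    return [
        CompartmentMap("WM", Volume(rng.normal(loc, scale, shape), aff),
                       np.ones(shape, bool))
        for _ in range(n_subjects)
    ]


def two_group_cohort(n_a, n_b):
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n_a + n_b)],
        "group": ["A"] * n_a + ["B"] * n_b,
    })


class TestBuildDesign:
    def test_cell_means_indicators(self):
        cohort = pd.DataFrame({
            "subject_id": list("abcdef"),
            "group": ["control", "control", "sMCI", "sMCI", "mMCI", "mMCI"],
        })
        d = build_design(cohort, groups=["control", "sMCI", "mMCI"])
        assert d.X.shape == (6, 3)
        assert np.array_equal(d.X.sum(axis=1), np.ones(6))
        assert d.group_column_map == {"control": 0, "sMCI": 1, "mMCI": 2}

    def test_covariates_centered(self):
        cohort = two_group_cohort(4, 4)
        cohort["age"] = [60, 70, 80, 65, 72, 68, 77, 63]
        d = build_design(cohort, ["age"])
        assert abs(d.X[:, 2].mean()) < 1e-12

    def test_education_becomes_two_dummies(self):
        cohort = two_group_cohort(3, 3)
        cohort["education"] = [1, 2, 3, 1, 2, 3]
        d = build_design(cohort, ["education"])
        assert d.column_names[-2:] == ["education_2", "education_3"]

    def test_constant_covariate_rank_error(self):
        cohort = two_group_cohort(4, 4)
        cohort["flat"] = 1.0
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(cohort, ["flat"])

    def test_contrast_vector_spec(self):
        cohort = two_group_cohort(3, 3)
        d = build_design(cohort)
        assert np.array_equal(contrast_vector(d, "A>B"), [1, -1])
        with pytest.raises(ValueError, match="unknown group"):
            contrast_vector(d, "A>C")


class TestFitGlm:
    def test_two_group_t_equals_pooled_t_oracle(self):
        """Cell-means contrast t equals the textbook pooled-variance
        two-sample t at every voxel (1e-10)."""
        rng = np.random.default_rng(0)
        maps = random_maps(rng, 14)
        cohort = two_group_cohort(8, 6)
        res = fit_glm(maps, build_design(cohort), "A>B")
        Y = np.stack([m.mtr.data.ravel() for m in maps])
        expected = pooled_two_sample_t(Y[:8], Y[8:])
        assert np.nanmax(np.abs(res.t_map.data.ravel() - expected)) < 1e-10
        assert res.df == 12

    def test_statsmodels_cross_check_single_voxel(self):
        """Independent OLS cross-check with covariates."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        maps = random_maps(rng, 20, shape=(2, 2, 2))
        cohort = two_group_cohort(10, 10)
        cohort["age"] = rng.normal(70, 5, 20)
        design = build_design(cohort, ["age"])
        res = fit_glm(maps, design, "A>B")
        y = np.array([m.mtr.data[0, 0, 0] for m in maps])
        fit = sm.OLS(y, design.X).fit()
        t_sm = fit.t_test(np.array([1.0, -1.0, 0.0]))
        assert res.t_map.data[0, 0, 0] == pytest.approx(
            float(np.asarray(t_sm.tvalue).ravel()[0]), rel=1e-10)

    def test_degenerate_voxel_flagged_invalid(self):
        rng = np.random.default_rng(2)
        maps = random_maps(rng, 8)
        for m in maps:  # identical value across subjects at one voxel
            m.mtr.data[1, 1, 1] = 42.0
        res = fit_glm(maps, build_design(two_group_cohort(4, 4)), "A>B")
        assert np.isnan(res.t_map.data[1, 1, 1])
        assert not res.mask[1, 1, 1]

    def test_joint_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        maps = random_maps(rng, 10)
        cohort = two_group_cohort(5, 5)
        res = fit_glm(maps, build_design(cohort), "A>B")
        perm = rng.permutation(10)
        cohort_p = cohort.iloc[perm].reset_index(drop=True)
        maps_p = [maps[i] for i in perm]
        res_p = fit_glm(maps_p, build_design(cohort_p), "A>B")
        assert np.allclose(res.t_map.data, res_p.t_map.data, equal_nan=True)

    def test_contrast_negation_flips_sign(self):
        rng = np.random.default_rng(4)
        maps = random_maps(rng, 10)
        d = build_design(two_group_cohort(5, 5))
        t1 = fit_glm(maps, d, np.array([1.0, -1.0])).t_map.data
        t2 = fit_glm(maps, d, np.array([-1.0, 1.0])).t_map.data
        assert np.allclose(t1, -t2, equal_nan=True)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(5)
        maps = random_maps(rng, 12)
        cohort = two_group_cohort(6, 6)
        cohort["age"] = rng.normal(70, 5, 12)
        design = build_design(cohort, ["age"])
        res = fit_glm(maps, design, "A>B")
        Y = np.stack([m.mtr.data.ravel() for m in maps])
        beta = np.stack([b.data.ravel() for b in res.beta_maps])
        resid = Y - design.X @ beta
        assert np.abs(design.X.T @ resid).max() < 1e-8 * np.linalg.norm(Y)

    def test_invalid_voxels_excluded_listwise(self):
        rng = np.random.default_rng(6)
        maps = random_maps(rng, 8)
        maps[3].mtr.data[0, 0, 0] = np.nan
        res = fit_glm(maps, build_design(two_group_cohort(4, 4)), "A>B")
        assert not res.mask[0, 0, 0]
        assert np.isnan(res.t_map.data[0, 0, 0])


class TestVoxelwiseRegression:
    def test_null_t_distribution_matches_student(self):
        """With a score unrelated to the maps the voxel-wise t follows
        Student-t(df): KS distance < 0.05 over 10^4 voxels, n = 69."""
        rng = np.random.default_rng(7)
        n = 69
        aff = np.eye(4)
        shape = (25, 20, 20)  # 10^4 voxels
        maps = [CompartmentMap("WM", Volume(rng.normal(40, 3, shape), aff),
                               np.ones(shape, bool)) for _ in range(n)]
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["x"] * n,
            "score": rng.normal(20, 5, n),
        })
        res = voxelwise_regression(maps, cohort, "score")
        t = res.t_map.data.ravel()
        ks = stats.kstest(t, stats.t(df=res.df).cdf).statistic
        assert ks < 0.05

    def test_planted_slope_recovered(self, default_phantom):
        """A score generated from ROI-mean MTR with slope 1/0.13 is
        recovered as an MTR-on-score slope of ~0.13."""
        link = ScoreLinkSpec(1, slope=1 / 0.13, intercept=0.0, noise_sd=0.5)
        cohort, vols = simulate_cohort(
            default_phantom, {"control": 35, "sMCI": 34}, (),
            NoiseSpec(1.5, 4.0, 21), (link,))
        maps = maps_from_store(cohort, vols)
        res = voxelwise_regression(maps, cohort, "score_delayed")
        roi = vols.labels.data == 1
        slopes = res.slope_map.data[roi]
        # analytic attenuation: slope_vox averages to 0.13 over the ROI
        assert slopes.mean() == pytest.approx(0.13, abs=0.04)

    def test_constant_score_rejected(self):
        rng = np.random.default_rng(8)
        maps = random_maps(rng, 6)
        cohort = two_group_cohort(3, 3)
        cohort["score"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            voxelwise_regression(maps, cohort, "score")

    def test_covariate_equal_to_score_rejected(self):
        rng = np.random.default_rng(9)
        maps = random_maps(rng, 8)
        cohort = two_group_cohort(4, 4)
        cohort["score"] = rng.normal(size=8)
        cohort["copy"] = cohort["score"]
        with pytest.raises(ValueError, match="rank deficient"):
            voxelwise_regression(maps, cohort, "score", ["copy"])

    def test_missing_scores_listwise_complete(self):
        rng = np.random.default_rng(10)
        maps = random_maps(rng, 12)
        cohort = two_group_cohort(6, 6)
        score = rng.normal(20, 5, 12)
        score[:3] = np.nan
        cohort["score"] = score
        res = voxelwise_regression(maps, cohort, "score")
        assert res.df == 9 - 2  # 9 complete rows, intercept + slope

    def test_r2_invariant_to_affine_score_rescaling(self):
        rng = np.random.default_rng(11)
        maps = random_maps(rng, 10)
        cohort = two_group_cohort(5, 5)
        cohort["score"] = rng.normal(size=10)
        r2a = voxelwise_regression(maps, cohort, "score").r2_map.data
        cohort["score"] = 3.7 * cohort["score"] - 12.0
        r2b = voxelwise_regression(maps, cohort, "score").r2_map.data
        assert np.allclose(r2a, r2b, atol=1e-10)

    def test_r2_within_bounds(self):
        rng = np.random.default_rng(12)
        maps = random_maps(rng, 10)
        cohort = two_group_cohort(5, 5)
        cohort["score"] = rng.normal(size=10)
        r2 = voxelwise_regression(maps, cohort, "score").r2_map.data
        assert np.nanmin(r2) >= 0 and np.nanmax(r2) <= 1


class TestExtractRoiFit:
    def _result(self, rng, shape=(4, 4, 4)):
        maps = random_maps(rng, 8, shape)
        cohort = two_group_cohort(4, 4)
        cohort["score"] = rng.normal(size=8)
        return voxelwise_regression(maps, cohort, "score"), shape

    def test_uniform_tfce_ties_broken_lexicographically(self):
        rng = np.random.default_rng(13)
        res, shape = self._result(rng)
        tfce = Volume(np.ones(shape), res.slope_map.affine)
        fit = extract_roi_fit(res, tfce, np.ones(shape, bool), k=3)
        assert fit.voxels == [(0, 0, 0), (0, 0, 1), (0, 0, 2)]

    def test_k1_is_argmax_voxel(self):
        rng = np.random.default_rng(14)
        res, shape = self._result(rng)
        tdata = rng.random(shape)
        tfce = Volume(tdata, res.slope_map.affine)
        fit = extract_roi_fit(res, tfce, np.ones(shape, bool), k=1)
        peak = np.unravel_index(np.argmax(tdata), shape)
        assert fit.voxels == [tuple(int(i) for i in peak)]
        assert fit.mean_slope == pytest.approx(res.slope_map.data[peak])

    def test_small_mask_uses_all_with_warning(self):
        rng = np.random.default_rng(15)
        res, shape = self._result(rng)
        mask = np.zeros(shape, bool)
        mask[0, 0, :2] = True
        tfce = Volume(rng.random(shape), res.slope_map.affine)
        with pytest.warns(UserWarning, match="using all"):
            fit = extract_roi_fit(res, tfce, mask, k=10)
        assert len(fit.voxels) == 2
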