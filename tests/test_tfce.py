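"""TFCE transform, permutation FWE inference, conjunction/disjunction."""

import numpy as np
import pandas as pd
import pytest

from mtconj import (
    EffectSpec, NoiseSpec, TFCEParams, Volume, build_design, cluster_table,
    conjunction, disjunction, permutation_fwe, simulate_cohort, tfce_transform,
)
from conftest import brute_force_tfce_signed, maps_from_store


class TestTfceTransform:
    def test_all_zero_map(self):
        out = tfce_transform(np.zeros((5, 5, 5)), np.ones((5, 5, 5), bool))
        assert not out.any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            tfce_transform(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))

    def test_single_voxel_closed_form_limit(self):
        """Isolated voxel of height h, E=.5, H=2: TFCE -> h^3/3 as
        dh -> 0 (integral of u^2); dh = h/1000 is within 0.5 %."""
        h = 3.7
        stat = np.zeros((7, 7, 7))
        stat[3, 3, 3] = h
        params = TFCEParams(dh=h / 1000)
        out = tfce_transform(stat, np.ones((7, 7, 7), bool), params)
        assert out[3, 3, 3] == pytest.approx(h**3 / 3, rel=0.005)
        assert out[0, 0, 0] == 0.0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_brute_force_oracle(self, connectivity):
        """Exact agreement (1e-9) with independent per-threshold
        component labeling on random 8^3 maps, signed."""
        rng = np.random.default_rng(connectivity)
        params = TFCEParams(connectivity=connectivity)
        for _ in range(10):
            stat = rng.standard_normal((8, 8, 8)) * 2
            mask = rng.random((8, 8, 8)) > 0.2
            mask[0, 0, 0] = True
            got = tfce_transform(stat, mask, params)
            expected = brute_force_tfce_signed(stat, mask,
                                               connectivity=connectivity)
            assert np.abs(got - expected).max() < 1e-9

    def test_monotone_in_voxel_height(self):
        """Raising any voxel's statistic never lowers any TFCE value."""
        rng = np.random.default_rng(99)
        stat = rng.standard_normal((6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        params = TFCEParams(dh=0.05)  # fixed grid so maps are comparable
        base = tfce_transform(np.maximum(stat, 0), mask, params)
        for _ in range(5):
            i, j, k = rng.integers(0, 6, 3)
            bumped = np.maximum(stat, 0).copy()
            bumped[i, j, k] += rng.uniform(0.1, 1.0)
            out = tfce_transform(bumped, mask, params)
            assert (out >= base - 1e-12).all()

    def test_riemann_sum_converges_with_dh(self):
        """Halving dh changes TFCE by O(dh)."""
        rng = np.random.default_rng(7)
        stat = np.abs(rng.standard_normal((6, 6, 6)))
        mask = np.ones((6, 6, 6), bool)
        outs = {}
        for n_steps in (50, 100, 200, 400):
            outs[n_steps] = tfce_transform(
                stat, mask, TFCEParams(dh=stat.max() / n_steps))
        d1 = np.abs(outs[100] - outs[50]).max()
        d2 = np.abs(outs[200] - outs[100]).max()
        d3 = np.abs(outs[400] - outs[200]).max()
        assert d3 < d2 < d1  # differences shrink as dh halves

    def test_signed_transform_negates_negative_part(self):
        stat = np.zeros((5, 5, 5))
        stat[1, 1, 1] = 2.0
        stat[3, 3, 3] = -2.0
        out = tfce_transform(stat, np.ones((5, 5, 5), bool), TFCEParams(dh=0.02))
        assert out[1, 1, 1] > 0
        assert out[3, 3, 3] == pytest.approx(-out[1, 1, 1])


class TestPermutationFwe:
    def _null_maps(self, seed, n_a=4, n_b=4, shape=(6, 6, 6)):
        rng = np.random.default_rng(seed)
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        from mtconj import CompartmentMap

        maps = [CompartmentMap("WM", Volume(rng.normal(40, 2, shape), aff),
                               np.ones(shape, bool)) for _ in range(n_a + n_b)]
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n_a + n_b)],
            "group": ["A"] * n_a + ["B"] * n_b,
        })
        return maps, cohort

    def test_exhaustive_enumeration_for_small_groups(self):
        """4 vs 4 subjects: only C(8,4)=70 relabelings exist; p-values
        are multiples of 1/70 and enumeration warns."""
        maps, cohort = self._null_maps(0)
        design = build_design(cohort)
        with pytest.warns(UserWarning, match="enumerating exactly"):
            inf = permutation_fwe(maps, design, "A>B",
                                  n_permutations=1000, seed=1)
        assert inf.n_permutations == 70
        p = inf.p_value
        assert p == pytest.approx(round(p * 70) / 70, abs=1e-12)

    def test_alpha_one_threshold_is_min(self):
        maps, cohort = self._null_maps(1)
        design = build_design(cohort)
        with pytest.warns(UserWarning):
            inf = permutation_fwe(maps, design, "A>B", n_permutations=100,
                                  alpha=1.0, seed=2)
        assert inf.fwe_threshold == pytest.approx(inf.max_null.min())

    def test_fixed_seed_bit_identical(self):
        maps, cohort = self._null_maps(2, n_a=8, n_b=8)
        design = build_design(cohort)
        a = permutation_fwe(maps, design, "A>B", n_permutations=120, seed=5)
        b = permutation_fwe(maps, design, "A>B", n_permutations=120, seed=5)
        assert np.array_equal(a.max_null, b.max_null)
        assert a.fwe_threshold == b.fwe_threshold
        assert np.array_equal(a.sig_mask, b.sig_mask)

    def test_covariates_stay_with_subjects(self):
        """The generic (covariate) path gives the same observed t-map as
        the fast two-group path and runs without error."""
        maps, cohort = self._null_maps(3, n_a=8, n_b=8)
        cohort = cohort.copy()
        rng = np.random.default_rng(0)
        cohort["age"] = rng.normal(70, 5, len(cohort))
        design = build_design(cohort, ["age"])
        inf = permutation_fwe(maps, design, "A>B", n_permutations=100, seed=3)
        from mtconj import fit_glm

        res = fit_glm(maps, design, "A>B")
        assert np.allclose(inf.t_map.data, np.nan_to_num(res.t_map.data),
                           atol=1e-10)


class TestConjunctionDisjunction:
    def _make_inference(self, sig, grid=(4, 4, 4)):
        from mtconj.tfce import TFCEInference

        vol = Volume(np.zeros(grid))
        return TFCEInference(vol, np.zeros(10), 0.0, sig, 10, 0, 0.05,
                             TFCEParams(), mask=np.ones(grid, bool))

    def test_identical_inferences_give_sig_mask(self):
        sig = np.zeros((4, 4, 4), bool)
        sig[1:3, 1:3, 1:3] = True
        inf = self._make_inference(sig)
        assert np.array_equal(conjunction(inf, inf), sig)

    def test_disjoint_masks_give_empty(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert not conjunction(self._make_inference(a),
                               self._make_inference(b)).any()

    def test_disjunction_returns_sig_mask(self):
        sig = np.zeros((4, 4, 4), bool)
        sig[2, 2, 2] = True
        assert np.array_equal(disjunction(self._make_inference(sig)), sig)

    def test_planted_conjunction_and_disjunction_structure(self, default_phantom):
        """Shared ROI-1 effect in both patient groups, ROI-2 effect only
        in mMCI: conjunction covers ROI 1 and stays out of ROI 2;
        disjunction targets ROI 2 (reduced scale: n=12/group, 300
        permutations, delta 4 pp)."""
        effects = (
            EffectSpec("sMCI", 1, -4.0), EffectSpec("mMCI", 1, -4.0),
            EffectSpec("mMCI", 2, -4.0),
        )
        cohort, vols = simulate_cohort(
            default_phantom, {"control": 12, "sMCI": 12, "mMCI": 12},
            effects, NoiseSpec(1.5, 4.0, 31))
        maps = maps_from_store(cohort, vols)
        design = build_design(cohort, groups=["control", "sMCI", "mMCI"])
        common = dict(mask=np.ones(default_phantom.grid_shape, bool),
                      n_permutations=300)
        inf_a = permutation_fwe(maps, design, "control>sMCI", seed=1, **common)
        inf_b = permutation_fwe(maps, design, "control>mMCI", seed=2, **common)
        conj = conjunction(inf_a, inf_b)
        roi1 = vols.labels.data == 1
        roi2 = vols.labels.data == 2
        assert conj[roi1].mean() >= 0.5
        assert conj[roi2].sum() == 0
        inf_ab = permutation_fwe(maps, design, "sMCI>mMCI", seed=3, **common)
        dis = disjunction(inf_ab)
        assert dis[roi2].any()
        assert not dis[roi1].any()


class TestMinStatConjunction:
    def test_min_stat_variant_finds_shared_effect(self, default_phantom):
        """The minimum-statistic conjunction (TFCE of the voxel-wise
        min-t map against its own permutation null) also recovers the
        shared ROI and is seed-reproducible."""
        from mtconj import conjunction_min_stat

        effects = (EffectSpec("sMCI", 1, -5.0), EffectSpec("mMCI", 1, -5.0))
        cohort, vols = simulate_cohort(
            default_phantom, {"control": 12, "sMCI": 12, "mMCI": 12},
            effects, NoiseSpec(1.5, 4.0, 41))
        maps = maps_from_store(cohort, vols)
        design = build_design(cohort, groups=["control", "sMCI", "mMCI"])
        inf = conjunction_min_stat(
            maps, design, "control>sMCI", "control>mMCI",
            mask=np.ones(default_phantom.grid_shape, bool),
            n_permutations=200, seed=4)
        roi1 = vols.labels.data == 1
        assert inf.sig_mask[roi1].any()
        assert not inf.sig_mask[vols.labels.data == 2].any()
        inf2 = conjunction_min_stat(
            maps, design, "control>sMCI", "control>mMCI",
            mask=np.ones(default_phantom.grid_shape, bool),
            n_permutations=200, seed=4)
        assert np.array_equal(inf.max_null, inf2.max_null)


class TestClusterTable:
    def _labels(self, grid=(6, 6, 6)):
        lab = np.zeros(grid)
        lab[0:2, 0:2, 0:2] = 1
        lab[4:6, 4:6, 4:6] = 2
        return Volume(lab)

    def test_empty_mask_empty_table(self):
        labels = self._labels()
        tbl = cluster_table(np.zeros((6, 6, 6), bool),
                            Volume(np.zeros((6, 6, 6))), labels)
        assert len(tbl) == 0

    def test_mask_equal_to_roi_gives_100_percent(self):
        labels = self._labels()
        sig = labels.data == 1
        tbl = cluster_table(sig, Volume(np.ones((6, 6, 6))), labels)
        assert len(tbl) == 1
        assert tbl.loc[0, "label1_pct"] == pytest.approx(100.0)
        assert tbl.loc[0, "label2_pct"] == pytest.approx(0.0)

    def test_two_separated_blobs_hand_count(self):
        labels = self._labels()
        sig = np.zeros((6, 6, 6), bool)
        sig[0, 0, 0:3] = True          # 3 voxels
        sig[5, 5, 4:6] = True          # 2 voxels, disjoint
        tfce = Volume(np.arange(216, dtype=float).reshape(6, 6, 6))
        tbl = cluster_table(sig, tfce, labels)
        assert sorted(tbl["n_voxels"]) == [2, 3]
        assert tbl["n_voxels"].sum() == int(sig.sum())
        # peak voxel carries the maximal TFCE within each cluster
        row = tbl.loc[tbl["n_voxels"] == 2].iloc[0]
        assert (row["peak_i"], row["peak_j"], row["peak_k"]) == (5, 5, 5)
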