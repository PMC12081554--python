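"""Feature extraction: the 384-feature layout, hand-enumerated texture
matrices, affine equivariance, shape/IST invariances and the ICC filter
against an ANOVA oracle."""

import numpy as np
import pandas as pd
import pytest

from radstab.features import (FAMILY_COUNTS, N_FEATURES_TOTAL, SEQUENCES,
                              FeatureTable, dice, discretise,
                              extract_features, glcm_matrix, gldm_matrix,
                              glrlm_matrix, glszm_matrix, icc_2_1,
                              icc_filter, ngtdm_table, shape_features)


class TestDiscretise:
    def test_integers_map_one_to_one(self):
        vol = np.arange(8, dtype=float).reshape(2, 2, 2)
        out = discretise(vol, np.ones((2, 2, 2), bool), 8)
        np.testing.assert_array_equal(np.sort(out.ravel()), np.arange(1, 9))

    def test_two_values_two_bins(self):
        vol = np.array([0.0, 10.0]).reshape(2, 1, 1)
        out = discretise(vol, np.ones((2, 1, 1), bool), 2)
        np.testing.assert_array_equal(out.ravel(), [1, 2])

    def test_affine_equivariance(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.8
        a = discretise(vol, mask, 16)
        b = discretise(5.0 * vol - 3.0, mask, 16)
        np.testing.assert_array_equal(a, b)

    def test_constant_region_flagged_as_level_one(self):
        vol = np.ones((3, 3, 3))
        with pytest.warns(UserWarning, match="constant"):
            out = discretise(vol, np.ones((3, 3, 3), bool), 8)
        assert np.all(out == 1)

    def test_bin_count_validated(self):
        with pytest.raises(ValueError):
            discretise(np.ones((2, 2, 2)), np.ones((2, 2, 2), bool), 1)


class TestTextureMatrices:
    def test_glcm_hand_enumeration(self):
        # 2x2x1 region, levels [[1,1],[1,2]]; distance-1 in-plane pairs
        lv = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        mask = np.ones((2, 2, 1), bool)
        # axis-0 neighbours: (1,1) and (1,2); symmetric counts
        m0 = glcm_matrix(lv, mask, (1, 0, 0), 2)
        np.testing.assert_array_equal(m0, [[2, 1], [1, 0]])
        # axis-1 neighbours: (1,1) and (1,2)
        m1 = glcm_matrix(lv, mask, (0, 1, 0), 2)
        np.testing.assert_array_equal(m1, [[2, 1], [1, 0]])
        # diagonal: (1,2) once -> symmetric [[0,1],[1,0]]
        md = glcm_matrix(lv, mask, (1, 1, 0), 2)
        np.testing.assert_array_equal(md, [[0, 1], [1, 0]])
        # joint maximum and contrast from the axis-0 matrix by hand:
        # p = [[.5,.25],[.25,0]]; max p = 0.5; contrast = sum (i-j)^2 p = 0.5
        from radstab.features import _glcm_features
        f = _glcm_features(m0)
        assert f["MaximumProbability"] == pytest.approx(0.5)
        assert f["Contrast"] == pytest.approx(0.5)

    def test_glrlm_hand_runs(self):
        # one line of levels 1 1 2 2 2: runs (1, len2) and (2, len3)
        lv = np.array([1, 1, 2, 2, 2]).reshape(5, 1, 1)
        mask = np.ones((5, 1, 1), bool)
        R = glrlm_matrix(lv, mask, (1, 0, 0), 2)
        expect = np.zeros((2, 3))
        expect[0, 1] = 1  # level 1, run length 2
        expect[1, 2] = 1  # level 2, run length 3
        np.testing.assert_array_equal(R, expect)

    def test_glszm_hand_zones(self):
        # two disconnected level-1 zones of sizes 2 and 1
        lv = np.zeros((5, 1, 1), int)
        mask = np.zeros((5, 1, 1), bool)
        lv[[0, 1, 3], 0, 0] = 1
        mask[[0, 1, 3], 0, 0] = True
        S = glszm_matrix(lv, mask, 1)
        np.testing.assert_array_equal(S, [[1, 1]])  # one size-1, one size-2

    def test_gldm_constant_region_fully_dependent(self):
        lv = np.ones((3, 3, 3), int)
        mask = np.ones((3, 3, 3), bool)
        D = gldm_matrix(lv, mask, 1)
        # the centre voxel has all 26 neighbours equal -> dependence 27
        assert D.shape == (1, 27)
        assert D[0, 26] == 1  # exactly one interior voxel

    def test_ngtdm_constant_region_zero_difference(self):
        lv = np.ones((3, 3, 3), int)
        mask = np.ones((3, 3, 3), bool)
        n_i, s_i = ngtdm_table(lv, mask, 1)
        assert n_i[0] == 27
        assert s_i[0] == 0.0


class TestExtraction:
    def test_layout_384_with_family_counts(self, phantom_cohort):
        _, vsets = phantom_cohort
        vs = vsets[0]
        s = extract_features(vs.volumes, vs.masks["wtv"], 32)
        assert len(s) == N_FEATURES_TOTAL == 384
        fams = pd.Series([n.split("_")[1] for n in s.index]).value_counts()
        for fam, count in FAMILY_COUNTS.items():
            assert fams[fam] == count * len(SEQUENCES)
        assert fams["shape"] == 12
        assert s.notna().all()

    def test_constant_region_degenerate_features(self):
        vols = {seq: np.full((8, 8, 8), 7.0) for seq in SEQUENCES}
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        with pytest.warns(UserWarning):
            s = extract_features(vols, mask, 8)
        assert s["T1W_firstorder_Variance_bin8"] == 0.0
        assert s["T1W_firstorder_Entropy_bin8"] == 0.0
        assert s["T1W_glcm_Contrast_bin8"] == 0.0

    def test_intensity_features_affine_invariant(self, phantom_cohort):
        _, vsets = phantom_cohort
        vs = vsets[0]
        s1 = extract_features(vs.volumes, vs.masks["wtv"], 32)
        s2 = extract_features({k: 2.5 * v + 11 for k, v in vs.volumes.items()},
                              vs.masks["wtv"], 32)
        texture = [n for n in s1.index if n.split("_")[1]
                   in ("glcm", "glrlm", "glszm", "gldm", "ngtdm")]
        np.testing.assert_allclose(s1[texture], s2[texture], rtol=1e-9)

    def test_shape_features_ignore_intensities_and_bins(self, phantom_cohort):
        _, vsets = phantom_cohort
        vs = vsets[0]
        shape_names = [f"T1CE_shape_{k}" for k in
                       shape_features(vs.masks["wtv"]).keys()]
        s_a = extract_features(vs.volumes, vs.masks["wtv"], 8)
        s_b = extract_features({k: 3 * v - 9 for k, v in vs.volumes.items()},
                               vs.masks["wtv"], 128)
        np.testing.assert_allclose(s_a[shape_names], s_b[shape_names],
                                   rtol=1e-12)

    def test_empty_mask_rejected(self, phantom_cohort):
        _, vsets = phantom_cohort
        with pytest.raises(ValueError, match="empty"):
            extract_features(vsets[0].volumes,
                             np.zeros_like(vsets[0].masks["wtv"]), 32)

    def test_sphere_shape_descriptors(self):
        zz, yy, xx = np.mgrid[:40, :40, :40]
        sph = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        f = shape_features(sph)
        assert f["Sphericity"] == pytest.approx(1.0, abs=0.1)
        assert f["VoxelVolume"] == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)
        assert f["Maximum3DDiameter"] == pytest.approx(20.0, abs=0.5)
        assert f["Elongation"] == pytest.approx(1.0, abs=0.05)


class TestIccFilter:
    def test_identical_tables_keep_everything(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)),
                          columns=[f"T1W_sim_f{i}" for i in range(4)])
        t = FeatureTable(df)
        assert icc_filter(t, FeatureTable(df.copy()), 0.8) == list(df.columns)

    def test_independent_noise_removed(self, rng):
        a = pd.DataFrame({"T1W_sim_good": rng.normal(size=30),
                          "T1W_sim_bad": rng.normal(size=30)})
        b = a.copy()
        b["T1W_sim_bad"] = rng.normal(size=30)  # second rater pure noise
        kept = icc_filter(FeatureTable(a), FeatureTable(b), 0.8)
        assert kept == ["T1W_sim_good"]

    def test_matches_anova_oracle_on_five_patients(self):
        # hand-sized data; oracle computes ICC(2,1) from raw ANOVA sums
        a = np.array([9.0, 6.0, 8.0, 7.0, 10.0])
        b = np.array([2.0, 1.0, 4.0, 1.0, 5.0])
        n, k = 5, 2
        Y = np.stack([a, b], axis=1)
        grand = Y.mean()
        ss_rows = k * ((Y.mean(1) - grand) ** 2).sum()
        ss_cols = n * ((Y.mean(0) - grand) ** 2).sum()
        ss_err = ((Y - Y.mean(1)[:, None] - Y.mean(0)[None, :] + grand) ** 2).sum()
        msr, msc, mse = ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + mse + k * (msc - mse) / n)
        assert icc_2_1(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin_reference(self, rng):
        import pingouin as pg
        a = rng.normal(size=20)
        b = a + rng.normal(0, 0.4, 20)
        df = pd.DataFrame({"t": np.repeat(np.arange(20), 2),
                           "r": ["A", "B"] * 20,
                           "s": np.stack([a, b], 1).ravel()})
        ref = pg.intraclass_corr(df, "t", "r", "s")
        ref_icc2 = ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_2_1(a, b) == pytest.approx(ref_icc2, abs=1e-10)

    def test_zero_variance_feature_removed_with_warning(self, rng):
        a = pd.DataFrame({"T1W_sim_flat": np.ones(10),
                          "T1W_sim_ok": rng.normal(size=10)})
        b = a.copy()
        with pytest.warns(UserWarning, match="undefined ICC"):
            kept = icc_filter(FeatureTable(a), FeatureTable(b), 0.8)
        assert kept == ["T1W_sim_ok"]

    def test_too_few_patients_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(2, 2)), columns=["a_x_1", "a_x_2"])
        with pytest.raises(ValueError, match="at least 3"):
            icc_filter(FeatureTable(df), FeatureTable(df.copy()), 0.8)


class TestDice:
    def test_identical_disjoint_and_half(self):
        a = np.zeros((4, 4, 1), bool)
        a[:2, :2, 0] = True            # |A| = 4
        assert dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[2:, 2:, 0] = True            # disjoint, |B| = 4
        assert dice(a, b) == 0.0
        c = np.zeros_like(a)
        c[:2, 1:3, 0] = True           # |C| = 4, |A^C| = 2
        assert dice(a, c) == 0.5

    def test_both_empty_is_one_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            assert dice(np.zeros((2, 2, 2), bool),
                        np.zeros((2, 2, 2), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((3, 2, 2), bool))


class TestFeatureTable:
    def test_metadata_parse_round_trip(self):
        df = pd.DataFrame(np.zeros((2, 3)), columns=[
            "T1W_glcm_Contrast_bin32", "FLAIR_firstorder_Mean_bin8",
            "T1CE_shape_Sphericity"])
        meta = FeatureTable(df).metadata()
        assert meta.loc["T1W_glcm_Contrast_bin32", "sequence"] == "T1W"
        assert meta.loc["T1W_glcm_Contrast_bin32", "bin_count"] == 32
        assert pd.isna(meta.loc["T1CE_shape_Sphericity", "bin_count"])

    def test_duplicate_names_rejected(self):
        df = pd.DataFrame(np.zeros((2, 2)), columns=["a_x_f", "a_x_f"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(df)

    def test_csv_round_trip(self, tmp_path, rng):
        df = pd.DataFrame(rng.normal(size=(3, 2)),
                          index=pd.Index(["p0", "p1", "p2"], name="patient_id"),
                          columns=["T1W_sim_f0", "T2W_sim_f1"])
        t = FeatureTable(df)
        t.to_csv(tmp_path / "f.csv")
        t2 = FeatureTable.from_csv(tmp_path / "f.csv")
        pd.testing.assert_frame_equal(t.values, t2.values)
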