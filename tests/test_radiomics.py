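"""Reference normalization, feature extraction, mRMR, survival labels."""

import numpy as np
import pandas as pd
import pytest

from qmrsynth.radiomics import (
    FeatureConfig,
    MRMRSelector,
    NormalizationError,
    _discretize,
    _first_order,
    _glcm,
    _mutual_info,
    _shape,
    extract_features,
    build_feature_table,
    label_subjects,
    normalize_by_reference,
    parse_feature_name,
    select_features_mrmr,
)


class TestNormalization:
    def test_scaling_and_fixed_point(self, tiny_record):
        img = tiny_record.weighted["T1w"]
        wm = tiny_record.label_mask("WM")
        out = normalize_by_reference(img, wm, tiny_record.hemisphere_of_tumor)
        nx = img.intensities.shape[0]
        contra = np.zeros_like(wm)
        if tiny_record.hemisphere_of_tumor == "left":
            contra[nx // 2:] = True
        else:
            contra[: nx // 2] = True
        ref = wm & contra
        assert abs(out.intensities[ref].mean() - 1.0) < 1e-9
        ratio = img.intensities[ref].mean()
        assert np.allclose(out.intensities, img.intensities / ratio)

    def test_reference_voxels_are_contralateral(self):
        """Mark hemispheres with distinct values and check which side sets
        the scale when the tumor is on the left."""
        arr = np.zeros((8, 4, 2))
        arr[:4] = 2.0   # left hemisphere
        arr[4:] = 5.0   # right hemisphere
        wm = np.ones((8, 4, 2), bool)
        out = normalize_by_reference(arr, wm, "left")
        assert np.allclose(out.intensities[4:], 1.0)  # right side mean -> 1

    def test_empty_reference_raises(self):
        arr = np.ones((4, 4, 2))
        wm = np.zeros((4, 4, 2), bool)
        wm[0, 0, 0] = True  # left-hemisphere WM only
        with pytest.raises(NormalizationError):
            normalize_by_reference(arr, wm, "left")  # needs right-side WM


class TestFeatureFamilies:
    def test_constant_roi_degenerate_texture(self):
        vol = np.full((4, 4, 4), 3.3)
        roi = np.ones((4, 4, 4), bool)
        fo = _first_order(vol[roi], 8)
        assert fo["std"] == pytest.approx(0.0, abs=1e-12)
        g = _glcm(vol, roi, 16)
        assert g["energy"] == pytest.approx(1.0)
        assert g["entropy"] == pytest.approx(0.0)

    def test_checkerboard_glcm_matches_pair_counting(self):
        """Exhaustive co-occurrence tally on a 4x4 single-slice patch."""
        patch = np.indices((4, 4, 1)).sum(axis=0) % 2  # checkerboard 0/1
        vol = patch.astype(float)
        roi = np.ones_like(vol, bool)
        got = _glcm(vol, roi, 2)
        # brute-force symmetric tally over the three unit offsets
        counts = np.zeros((2, 2))
        q = patch
        for off in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            for i in range(4 - off[0]):
                for j in range(4 - off[1]):
                    for k in range(1 - off[2]):
                        a = q[i, j, k]
                        b = q[i + off[0], j + off[1], k + off[2]]
                        counts[a, b] += 1
                        counts[b, a] += 1
        p = counts / counts.sum()
        ii, jj = np.indices((2, 2))
        assert got["contrast"] == pytest.approx(((ii - jj) ** 2 * p).sum())
        assert got["energy"] == pytest.approx((p**2).sum())

    def test_sphere_more_spherical_than_elongated_ellipsoid(self):
        def ellipsoid_mask(rx, ry, rz, n=33):
            g = np.indices((n, n, n)) - n // 2
            return (g[0] / rx) ** 2 + (g[1] / ry) ** 2 + (g[2] / rz) ** 2 <= 1

        sph = _shape(ellipsoid_mask(10, 10, 10))
        ell = _shape(ellipsoid_mask(15, 5, 5))
        assert sph["sphericity"] == pytest.approx(1.0, abs=0.1)
        assert sph["sphericity"] > ell["sphericity"]
        # analytic check: volume within discretization tolerance of 4/3 pi r^3
        assert sph["volume"] == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_empty_roi_yields_nan(self):
        out = _shape(np.zeros((3, 3, 3), bool))
        assert np.isnan(out["volume"])


class TestExtraction:
    def test_feature_row_is_deterministic(self, tiny_record):
        a = extract_features(tiny_record)
        b = extract_features(tiny_record)
        assert a.equals(b)
        assert not a.isna().any()

    def test_column_names_parse_into_tuples(self, tiny_record):
        row = extract_features(tiny_record)
        for name in row.index:
            contrast, roi, family, feat = parse_feature_name(name)
            assert family in ("firstorder", "glcm", "shape")

    def test_replaced_channel_isolation(self, tiny_record):
        """Replacing one contrast changes only that contrast's columns."""
        from qmrsynth.physics import WeightedImage
        rng = np.random.default_rng(0)
        fake = tiny_record.weighted["FLAIR"]
        noisy = WeightedImage(fake.intensities * (1 + 0.1 * rng.random(fake.intensities.shape)),
                              "FLAIR", fake.params, fake.mask)
        base = extract_features(tiny_record)
        repl = extract_features(tiny_record, replaced_images={"FLAIR": noisy})
        for name in base.index:
            contrast = parse_feature_name(name)[0]
            if contrast == "FLAIR":
                continue
            assert base[name] == repl[name]
        flair_cols = [n for n in base.index if parse_feature_name(n)[0] == "FLAIR"]
        assert any(base[n] != repl[n] for n in flair_cols)

    def test_table_shape(self, small_cohort):
        records, _ = small_cohort
        cfg = FeatureConfig(rois=("ED", "TC", "WT"))
        table = build_feature_table(records, feature_config=cfg)
        assert table.shape[0] == len(records)
        assert table.shape[1] == 4 * 3 * 18 + 3 * 3  # contrasts x rois x feats + shape


class TestMRMR:
    def test_perfect_feature_selected_first(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 80)
        X = pd.DataFrame(rng.random((80, 6)), columns=[f"n{i}" for i in range(6)])
        X["signal"] = y + 0.01 * rng.random(80)
        picked = select_features_mrmr(X, y, k=3)
        assert picked[0] == "signal"
        # oracle: its MI must exceed every noise feature's MI
        mi_sig = _mutual_info(_discretize(X["signal"].to_numpy()), y)
        for c in X.columns:
            if c != "signal":
                assert mi_sig > _mutual_info(_discretize(X[c].to_numpy()), y)

    def test_duplicate_of_first_pick_never_second(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        base = y + 0.05 * rng.random(60)
        X = pd.DataFrame({
            "a_signal": base,
            "b_duplicate": base.copy(),
            "c_weak": y * 0.5 + rng.random(60),
            "d_noise": rng.random(60),
            "e_noise": rng.random(60),
        })
        picked = select_features_mrmr(X, y, k=3)
        assert picked[0] == "a_signal"
        assert picked[1] != "b_duplicate"

    def test_exhaustion_returns_full_ranking(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 40)
        X = pd.DataFrame(rng.random((40, 5)), columns=list("abcde"))
        picked = select_features_mrmr(X, y, k=5)
        assert sorted(picked) == list("abcde")

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            MRMRSelector(k=0).fit(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1])

    def test_transformer_interface(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 50)
        X = pd.DataFrame(rng.random((50, 4)), columns=list("wxyz"))
        sel = MRMRSelector(k=2).fit(X, y)
        assert sel.transform(X).shape == (50, 2)


class TestLabels:
    def test_threshold_is_strict(self):
        table = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "survival_days": [481, 480, 300, 500],
            "censored": [0, 0, 1, 1],
        })
        labels, excluded = label_subjects(table, 480)
        assert labels["a"] == 1
        assert labels["b"] == 0          # exactly 480 days is the short class
        assert "c" not in labels.index   # censored before threshold: excluded
        assert labels["d"] == 1          # censored past threshold: survivor
        assert list(excluded["subject_id"]) == ["c"]

    def test_short_policy_labels_censored_zero(self):
        table = pd.DataFrame({"subject_id": ["a"], "survival_days": [100],
                              "censored": [1]})
        labels, _ = label_subjects(table, 480, censor_policy="short")
        assert labels["a"] == 0

    def test_empty_labeled_set_raises(self):
        table = pd.DataFrame({"subject_id": ["a"], "survival_days": [100],
                              "censored": [1]})
        with pytest.raises(ValueError):
            label_subjects(table, 480)
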