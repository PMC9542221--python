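"""Phantom generator: geometry, physics constraints, noise, survival law."""

import numpy as np
import pytest

from qmrsynth.phantom import (
    CohortSpec,
    LABEL_CODES,
    LesionSpec,
    SpecError,
    TissueModel,
    assign_survival,
    generate_cohort,
    generate_phantom,
    simulate_subject_images,
)
from qmrsynth.physics import simulate_contrast, default_protocol
from qmrsynth.radiomics import _discretize, _mutual_info


@pytest.fixture(scope="module")
def survival_cohort():
    """200 map-only phantoms (no images) for survival-law statistics."""
    rng = np.random.default_rng(42)
    cs = rng.uniform(-0.8, 0.8, 200)
    return [generate_phantom(seed=1000 + i, grid_shape=(32, 32, 10),
                             texture_corr=float(cs[i]), subject_id=f"s{i:03d}")
            for i in range(200)]


class TestGeometry:
    def test_determinism(self):
        a = generate_phantom(seed=3, grid_shape=(32, 32, 10))
        b = generate_phantom(seed=3, grid_shape=(32, 32, 10))
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.maps.t1, b.maps.t1)
        assert a.hemisphere_of_tumor == b.hemisphere_of_tumor

    def test_zero_radius_lesion_has_no_tumor(self):
        rec = generate_phantom(seed=1, grid_shape=(32, 32, 10),
                               lesion_spec=LesionSpec(ed_radius=0, tc_radius=0,
                                                      net_radius=0))
        for name in ("ET", "NET", "ED"):
            assert not rec.label_mask(name).any()

    def test_wt_fraction_matches_direct_count(self, tiny_record):
        labels = tiny_record.labels
        brute = sum(int((labels == LABEL_CODES[n]).sum()) for n in ("ET", "NET", "ED"))
        assert int(tiny_record.wt_mask.sum()) == brute
        assert brute > 0

    def test_label_partition_covers_foreground(self, tiny_record):
        fg = tiny_record.maps.foreground_mask
        counts = sum(int((tiny_record.labels == code).sum())
                     for name, code in LABEL_CODES.items() if name != "background")
        assert counts == int(fg.sum())

    def test_tumor_confined_to_one_hemisphere(self, tiny_record):
        xs = np.nonzero(tiny_record.wt_mask)[0]
        mid = tiny_record.labels.shape[0] // 2
        if tiny_record.hemisphere_of_tumor == "left":
            assert xs.max() < mid
        else:
            assert xs.min() >= mid

    def test_oversized_lesion_rejected(self):
        with pytest.raises(SpecError):
            generate_phantom(seed=0, grid_shape=(24, 24, 8),
                             lesion_spec=LesionSpec(ed_radius=12, radius_jitter=0))

    def test_physical_ordering_t1_ge_t2(self, tiny_record):
        fg = tiny_record.maps.foreground_mask
        assert np.all(tiny_record.maps.t1[fg] >= tiny_record.maps.t2[fg])

    def test_tissue_model_ordering_enforced(self):
        bad = {"WM": (2000.0, 80.0, 0.7), "GM": (1000.0, 100.0, 0.85),
               "CSF": (4000.0, 2000.0, 1.0), "ET": (1500.0, 130.0, 0.92),
               "NET": (1400.0, 120.0, 0.88), "ED": (1300.0, 110.0, 0.9)}
        with pytest.raises(SpecError):
            TissueModel(classes=bad)


class TestImages:
    def test_sigma_zero_reproduces_ideal_exactly(self, tiny_record, protocol):
        ideal = simulate_contrast(tiny_record.maps, "T2w", protocol)
        assert np.array_equal(tiny_record.weighted["T2w"].intensities,
                              ideal.intensities)

    def test_rician_bias_nonnegative_at_bright_voxel(self):
        """Monte-Carlo: E[sqrt((S+e1)^2+e2^2)] >= S for Gaussian e."""
        rng = np.random.default_rng(9)
        s, sigma, n = 0.5, 0.1, 10_000
        draws = np.sqrt((s + rng.normal(0, sigma, n)) ** 2
                        + rng.normal(0, sigma, n) ** 2)
        assert draws.mean() >= s

    def test_noise_seeds_separate_from_geometry(self, protocol):
        a = generate_phantom(seed=5, grid_shape=(32, 32, 10))
        b = generate_phantom(seed=5, grid_shape=(32, 32, 10))
        simulate_subject_images(a, protocol, noise_sigma=0.05, seed=1)
        simulate_subject_images(b, protocol, noise_sigma=0.05, seed=2)
        assert np.array_equal(a.maps.t1, b.maps.t1)
        assert not np.array_equal(a.weighted["T1w"].intensities,
                                  b.weighted["T1w"].intensities)

    def test_contrast_enhancement_brightens_et_only(self, tiny_record):
        et = tiny_record.label_mask("ET")
        t1w = tiny_record.weighted["T1w"].intensities
        t1wc = tiny_record.weighted["T1w_c"].intensities
        assert np.all(t1wc[et] > t1w[et])
        rest = tiny_record.maps.foreground_mask & ~et
        assert np.array_equal(t1wc[rest], t1w[rest])


class TestSurvival:
    def test_reproducible_given_spec(self):
        spec = CohortSpec(n_subjects=4, grid_shape=(32, 32, 10), seed=17)
        _, t1 = generate_cohort(spec)
        _, t2 = generate_cohort(spec)
        assert t1.equals(t2)

    def test_zero_censor_rate(self, survival_cohort):
        spec = CohortSpec(n_subjects=8, grid_shape=(32, 32, 10), censor_rate=0.0)
        recs = assign_survival(survival_cohort[:8], spec, seed=0)
        assert all(r.censored == 0 for r in recs)

    def test_all_censored_configuration_rejected(self):
        with pytest.raises(SpecError):
            CohortSpec(n_subjects=4, censor_rate=1.0)

    def test_negative_volume_coefficient_shortens_survival(self, survival_cohort):
        spec = CohortSpec(n_subjects=200, grid_shape=(32, 32, 10),
                          beta_volume=-0.8, beta_texture=0.0, censor_rate=0.0,
                          survival_sigma=0.2)
        recs = assign_survival(list(survival_cohort), spec, seed=3)
        vols = np.array([r.wt_mask.sum() for r in recs])
        days = np.array([r.survival_days for r in recs])
        big = days[vols > np.median(vols)]
        small = days[vols <= np.median(vols)]
        assert np.median(big) < np.median(small)

    def test_zero_effects_give_label_independence(self, survival_cohort):
        """Null generator: survival carries no image information."""
        spec = CohortSpec(n_subjects=200, grid_shape=(32, 32, 10),
                          beta_volume=0.0, beta_texture=0.0, censor_rate=0.0)
        recs = assign_survival(list(survival_cohort), spec, seed=4)
        days = np.array([r.survival_days for r in recs])
        cs = np.array([r.covariates["texture_corr"] for r in recs])
        assert abs(np.corrcoef(cs, np.log(days))[0, 1]) < 0.15

    def test_planted_texture_beats_random_covariate(self, survival_cohort):
        """MI between the planted covariate and the 480-day label exceeds
        that of an unrelated random covariate."""
        spec = CohortSpec(n_subjects=200, grid_shape=(32, 32, 10), censor_rate=0.0)
        recs = assign_survival(list(survival_cohort), spec, seed=5)
        label = np.array([int(r.survival_days > 480) for r in recs])
        planted = np.array([r.covariates["texture_corr"] for r in recs])
        rng = np.random.default_rng(6)
        random_cov = rng.random(len(recs))
        mi_planted = _mutual_info(_discretize(planted), label)
        mi_random = _mutual_info(_discretize(random_cov), label)
        assert mi_planted > mi_random
        assert 0 < label.mean() < 1  # both classes present


class TestCohort:
    def test_default_emulates_24_subject_test_cohort(self):
        spec = CohortSpec()
        assert spec.n_subjects == 24 and spec.threshold_days == 480

    def test_minimal_cohort_runs(self):
        spec = CohortSpec(n_subjects=2, grid_shape=(32, 32, 10), seed=1)
        records, table = generate_cohort(spec)
        assert len(records) == 2 and len(table) == 2
        assert set(table.columns) == {"subject_id", "survival_days", "censored"}

    def test_correlated_edema_mode_modulates_flair_variance(self, protocol):
        """The planted correlation shifts FLAIR edema texture energy much
        more than T1w's (the channel-specific survival signal)."""
        def ed_std(c, contrast):
            vals = []
            for s in range(4):
                r = generate_phantom(seed=60 + s, grid_shape=(48, 48, 12),
                                     texture_corr=c)
                img = simulate_contrast(r.maps, contrast, protocol)
                vals.append(img.intensities[r.label_mask("ED")].std()
                            / img.intensities[r.label_mask("ED")].mean())
            return np.mean(vals)

        flair_ratio = ed_std(-0.8, "FLAIR") / ed_std(0.8, "FLAIR")
        t1w_ratio = ed_std(-0.8, "T1w") / ed_std(0.8, "T1w")
        assert flair_ratio > 1.2          # strong response in FLAIR
        assert abs(np.log(t1w_ratio)) < abs(np.log(flair_ratio)) / 2
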