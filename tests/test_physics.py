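"""Closed-form signal model identities and the MAE synthesis loss."""

import numpy as np
import pytest

from qmrsynth.physics import (
    AcquisitionParams,
    ConfigError,
    DomainError,
    ParameterError,
    RelaxometryMaps,
    WeightedImage,
    default_protocol,
    mae_image,
    simulate_contrast,
    simulate_ir_se,
    simulate_spin_echo,
    synthesis_loss,
)


def _maps(t1, t2, pd, shape=(2, 2, 1)):
    return RelaxometryMaps(np.full(shape, float(t1)), np.full(shape, float(t2)),
                           np.full(shape, float(pd)), np.ones(shape, bool))


class TestSpinEcho:
    def test_limiting_case_recovers_pd(self):
        """TE -> 0 and TR -> inf leave only the proton density."""
        maps = _maps(1000, 100, 0.83)
        img = simulate_spin_echo(maps, AcquisitionParams("SE", te=1e-9, tr=1e9))
        assert np.allclose(img.intensities, 0.83, rtol=1e-9)

    def test_zero_pd_gives_zero_signal(self):
        img = simulate_spin_echo(_maps(800, 90, 0.0),
                                 AcquisitionParams("SE", te=50, tr=2000))
        assert np.all(img.intensities == 0)

    def test_scalar_oracle(self):
        """Direct evaluation of S = PD (1 - e^{-TR/T1}) e^{-TE/T2}."""
        img = simulate_spin_echo(_maps(1000, 100, 1.0),
                                 AcquisitionParams("SE", te=100, tr=4000))
        expected = (1 - np.exp(-4.0)) * np.exp(-1.0)
        assert np.allclose(img.intensities, expected, rtol=1e-12)

    def test_monotone_in_tr_and_te(self):
        maps = _maps(900, 80, 1.0)
        trs = [500, 1000, 2000, 4000]
        s_tr = [simulate_spin_echo(maps, AcquisitionParams("SE", 10, tr)).intensities[0, 0, 0]
                for tr in trs]
        assert np.all(np.diff(s_tr) > 0)
        tes = [10, 40, 80, 160]
        s_te = [simulate_spin_echo(maps, AcquisitionParams("SE", te, 5000)).intensities[0, 0, 0]
                for te in tes]
        assert np.all(np.diff(s_te) < 0)

    @pytest.mark.parametrize("scale", [0.25, 2.0, 7.5])
    def test_degree_one_homogeneity_in_pd(self, scale):
        p = AcquisitionParams("SE", te=30, tr=1500)
        base = simulate_spin_echo(_maps(1200, 110, 0.5), p).intensities
        scaled = simulate_spin_echo(_maps(1200, 110, 0.5 * scale), p).intensities
        assert np.allclose(scaled, scale * base, rtol=1e-12)


class TestIRSE:
    def test_inversion_null_point(self):
        """TI = T1 ln 2 under very long TR nulls the tissue."""
        t1 = 1400.0
        img = simulate_ir_se(_maps(t1, 100, 1.0),
                             AcquisitionParams("IR_SE", te=10, tr=1e9, ti=t1 * np.log(2)))
        assert np.allclose(img.intensities, 0.0, atol=1e-9)

    def test_long_ti_limit_matches_spin_echo(self):
        maps = _maps(1000, 100, 1.0)
        ir = simulate_ir_se(maps, AcquisitionParams("IR_SE", te=50, tr=2e9, ti=1e9))
        se = simulate_spin_echo(maps, AcquisitionParams("SE", te=50, tr=2e9))
        assert np.allclose(ir.intensities, se.intensities, rtol=1e-6)

    def test_flair_suppresses_long_t1_fluid(self):
        """CSF-like tissue is darker than WM-like tissue at equal PD."""
        flair = AcquisitionParams("IR_SE", te=140, tr=9000, ti=2200)
        csf = simulate_ir_se(_maps(4000, 2000, 1.0), flair).intensities[0, 0, 0]
        wm = simulate_ir_se(_maps(600, 80, 1.0), flair).intensities[0, 0, 0]
        assert csf < wm

    def test_nonnegative_and_continuous_across_null(self):
        t1 = 1000.0
        tis = np.linspace(0.5 * t1 * np.log(2), 1.5 * t1 * np.log(2), 101)
        vals = [simulate_ir_se(_maps(t1, 90, 1.0),
                               AcquisitionParams("IR_SE", 10, 1e7, ti)).intensities[0, 0, 0]
                for ti in tis]
        vals = np.array(vals)
        assert np.all(vals >= 0)
        steps = np.abs(np.diff(vals))
        assert steps.max() < 5 * np.median(steps)  # no jump at the null

    def test_missing_ti_rejected(self):
        with pytest.raises(ParameterError):
            AcquisitionParams("IR_SE", te=10, tr=5000)


class TestDispatch:
    def test_flair_routes_to_ir_se(self, uniform_maps, protocol):
        img = simulate_contrast(uniform_maps, "FLAIR", protocol)
        assert img.params.sequence == "IR_SE"

    def test_t2w_preset_makes_csf_brighter_than_wm(self, protocol):
        """Evaluated directly from the closed form at the tissue triples."""
        csf = simulate_contrast(_maps(4000, 2000, 1.0), "T2w", protocol)
        wm = simulate_contrast(_maps(600, 80, 0.7), "T2w", protocol)
        assert csf.intensities[0, 0, 0] > wm.intensities[0, 0, 0]

    def test_missing_preset_is_config_error(self, uniform_maps, protocol):
        partial = {k: v for k, v in protocol.items() if k != "T1w_c"}
        with pytest.raises(ConfigError):
            simulate_contrast(uniform_maps, "T1w_c", partial)


class TestLoss:
    def test_mae_hand_arithmetic(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 2.0, 5.0])
        assert mae_image(a, b, np.ones(3, bool)) == pytest.approx(1.0)
        assert mae_image(a, a, np.ones(3, bool)) == 0.0

    def test_worst_single_pixel_never_below_full_mae(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(12), rng.random(12)
        full = mae_image(a, b, np.ones(12, bool))
        singles = []
        for i in range(12):
            m = np.zeros(12, bool)
            m[i] = True
            singles.append(mae_image(a, b, m))
        assert max(singles) >= full

    def test_empty_mask_raises(self):
        with pytest.raises(DomainError):
            mae_image(np.ones(3), np.ones(3), np.zeros(3, bool))

    def test_batch_reduction_and_symmetry(self):
        rng = np.random.default_rng(1)
        pairs = [(rng.random(6), rng.random(6)) for _ in range(3)]
        maes = [mae_image(a, b, np.ones(6, bool)) for a, b in pairs]
        acq = [p[0] for p in pairs]
        syn = [p[1] for p in pairs]
        masks = [np.ones(6, bool)] * 3
        assert synthesis_loss(acq[:1], syn[:1], masks[:1]) == pytest.approx(maes[0])
        assert synthesis_loss(acq[:2], syn[:2], masks[:2]) == pytest.approx(
            (maes[0] + maes[1]) / 2)
        # permutation invariance, brute force over all 6 orders
        import itertools
        ref = synthesis_loss(acq, syn, masks)
        for perm in itertools.permutations(range(3)):
            assert synthesis_loss([acq[i] for i in perm], [syn[i] for i in perm],
                                  [masks[i] for i in perm]) == pytest.approx(ref)
        with pytest.raises(DomainError):
            synthesis_loss([], [])

    def test_loss_nonnegative_zero_iff_identical(self):
        rng = np.random.default_rng(2)
        a = [rng.random(5) for _ in range(2)]
        assert synthesis_loss(a, [x.copy() for x in a],
                              [np.ones(5, bool)] * 2) == 0.0
        b = [x + 0.1 for x in a]
        assert synthesis_loss(a, b, [np.ones(5, bool)] * 2) > 0


class TestValidation:
    def test_te_must_be_below_tr(self):
        with pytest.raises(ParameterError):
            AcquisitionParams("SE", te=500, tr=400)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ParameterError):
            AcquisitionParams("SE", te=-1, tr=400)

    def test_background_zero_enforced(self):
        shape = (3, 3, 1)
        mask = np.zeros(shape, bool)
        mask[1, 1, 0] = True
        t1 = np.where(mask, 900.0, 5.0)  # nonzero background is invalid
        maps = RelaxometryMaps(t1, np.where(mask, 80.0, 0.0),
                               np.where(mask, 1.0, 0.0), mask)
        with pytest.raises(ParameterError):
            maps.validate()

    def test_weighted_image_mask_shape_checked(self):
        with pytest.raises(Exception):
            WeightedImage(np.ones((2, 2)), "T1w",
                          AcquisitionParams("SE", 10, 500), np.ones((3, 3), bool))
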