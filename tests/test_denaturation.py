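"""GdnHCl calibration, enhancement correction and transition analysis."""

import numpy as np
import pytest

from thtbind.denaturation import (
    NoTransitionError, bound_fluorescence_profile, free_dye_enhancement,
    gdnhcl_from_ri, ri_from_gdnhcl, transition_points, DenaturationSeries,
)
from thtbind.simulate import GeneratorTruth, simulate_denaturation


class TestRefractiveIndexCalibration:
    def test_zero_increment_is_zero_molar(self):
        assert gdnhcl_from_ri(0.0) == 0.0

    @pytest.mark.parametrize("conc", [0.5, 1.0, 3.0, 5.5])
    def test_round_trip_identity(self, conc):
        assert gdnhcl_from_ri(ri_from_gdnhcl(conc)) == pytest.approx(
            conc, abs=1e-6)

    def test_monotone_over_calibration_range(self):
        dn = np.linspace(0, 0.1, 200)
        c = np.array([gdnhcl_from_ri(x) for x in dn])
        assert np.all(np.diff(c) > 0)

    def test_beyond_calibration_raises(self):
        with pytest.raises(ValueError, match="calibration"):
            gdnhcl_from_ri(0.2)
        with pytest.raises(ValueError):
            ri_from_gdnhcl(8.0)


class TestFreeDyeEnhancement:
    def test_reproduces_threefold_gain_at_6M(self):
        c = np.arange(0.0, 6.5, 0.5)
        f = 100.0 * (1 + 2 * c / 6.0)  # threefold at 6 M
        e = free_dye_enhancement(c, f)
        assert e(6.0) == pytest.approx(3.0, rel=1e-6)
        assert e(0.0) == pytest.approx(1.0)

    def test_constant_curve_is_unity(self):
        c = np.arange(0.0, 6.5, 0.5)
        e = free_dye_enhancement(c, np.full(c.size, 42.0))
        np.testing.assert_allclose(e(c), 1.0)

    def test_non_monotone_curve_isotonized_with_warning(self):
        c = np.arange(0.0, 6.5, 0.5)
        f = 1 + 2 * c / 6.0
        f[4] = 0.6  # large dip
        with pytest.warns(UserWarning, match="isotonic"):
            e = free_dye_enhancement(c, f)
        assert np.all(np.diff(e(c)) >= -1e-12)

    def test_deterministic_for_same_input(self):
        rng = np.random.default_rng(0)
        c = np.arange(0.0, 6.5, 0.5)
        f = (1 + 2 * c / 6.0) * (1 + rng.normal(0, 0.01, c.size))
        f[0] = 1.0
        e1, e2 = free_dye_enhancement(c, f), free_dye_enhancement(c, f)
        np.testing.assert_array_equal(e1(c), e2(c))

    def test_requires_zero_point(self):
        with pytest.raises(ValueError, match="c = 0"):
            free_dye_enhancement([0.5, 1.0, 2.0], [1.0, 1.1, 1.3])


class TestBoundProfile:
    def test_normalized_to_unity_at_zero(self):
        truth = GeneratorTruth(seed=0)
        data = simulate_denaturation(truth)
        enh = free_dye_enhancement(data.free_curve_conc_M,
                                   data.free_curve_intensity)
        series = bound_fluorescence_profile(data.points, enh)
        assert series.bound_F[0] == pytest.approx(1.0)

    def test_collapse_reaches_near_zero_past_transition(self):
        truth = GeneratorTruth(seed=1, denat_c_half_M=2.0)
        data = simulate_denaturation(truth)
        enh = free_dye_enhancement(data.free_curve_conc_M,
                                   data.free_curve_intensity)
        series = bound_fluorescence_profile(data.points, enh)
        late = series.gdnhcl_M >= 4.0
        assert np.all(np.abs(series.bound_F[late]) < 0.05)

    def test_constant_truth_gives_flat_profile(self):
        truth = GeneratorTruth(seed=2, denat_c_half_M=2.0,
                               denat_width_M=0.4, denat_noise_frac=0.0)
        # push the transition far beyond the measured range
        truth = GeneratorTruth(seed=2, denat_c_half_M=2.0,
                               denat_width_M=0.4, denat_noise_frac=0.0,
                               denat_conc_M=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5))
        data = simulate_denaturation(truth)
        enh = free_dye_enhancement(data.free_curve_conc_M,
                                   data.free_curve_intensity)
        series = bound_fluorescence_profile(data.points, enh)
        assert np.all(series.bound_F > 0.85)

    def test_missing_pair_raises(self):
        truth = GeneratorTruth(seed=3)
        data = simulate_denaturation(truth)
        import dataclasses
        broken = [dataclasses.replace(data.points[0], sample_emission=None)] \
            + list(data.points[1:])
        enh = free_dye_enhancement(data.free_curve_conc_M,
                                   data.free_curve_intensity)
        with pytest.raises(ValueError, match="missing"):
            bound_fluorescence_profile(broken, enh)


class TestTransitionPoints:
    def test_midpoint_recovered(self):
        halves = []
        for seed in range(15):
            truth = GeneratorTruth(seed=seed, denat_c_half_M=2.0)
            data = simulate_denaturation(truth)
            enh = free_dye_enhancement(data.free_curve_conc_M,
                                       data.free_curve_intensity)
            res = transition_points(bound_fluorescence_profile(data.points, enh))
            halves.append(res.c_half_M)
        assert np.mean(halves) == pytest.approx(2.0, abs=0.1)

    @pytest.mark.parametrize("c_half", [1.0, 3.0, 4.5])
    def test_midpoint_recovery_across_range(self, c_half):
        errs = []
        for seed in range(10):
            truth = GeneratorTruth(seed=seed, denat_c_half_M=c_half)
            data = simulate_denaturation(truth)
            enh = free_dye_enhancement(data.free_curve_conc_M,
                                       data.free_curve_intensity)
            res = transition_points(bound_fluorescence_profile(data.points, enh))
            errs.append(abs(res.c_half_M - c_half))
        assert np.median(errs) < 0.15

    def test_two_phase_sets_early_decay_flag(self):
        truth = GeneratorTruth(seed=4, denat_two_phase=True)
        data = simulate_denaturation(truth)
        enh = free_dye_enhancement(data.free_curve_conc_M,
                                   data.free_curve_intensity)
        res = transition_points(bound_fluorescence_profile(data.points, enh))
        assert res.early_decay_flag

    def test_single_phase_does_not_flag(self):
        truth = GeneratorTruth(seed=5)
        data = simulate_denaturation(truth)
        enh = free_dye_enhancement(data.free_curve_conc_M,
                                   data.free_curve_intensity)
        res = transition_points(bound_fluorescence_profile(data.points, enh))
        assert not res.early_decay_flag

    def test_increasing_profile_raises(self):
        series = DenaturationSeries(
            gdnhcl_M=np.arange(0.0, 6.5, 0.5),
            bound_F=np.linspace(1.0, 1.5, 13),
            turbidity=None, rls=None,
            free_enhancement=np.ones(13))
        with pytest.raises(NoTransitionError):
            transition_points(series)

    def test_needs_six_points(self):
        series = DenaturationSeries(
            gdnhcl_M=np.array([0.0, 1.0, 2.0, 3.0]),
            bound_F=np.array([1.0, 0.8, 0.3, 0.05]),
            turbidity=None, rls=None, free_enhancement=np.ones(4))
        with pytest.raises(ValueError, match="6 points"):
            transition_points(series)
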