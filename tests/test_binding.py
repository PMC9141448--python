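"""Concentration arithmetic, Scatchard analysis and isotherm fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thtbind.binding import (
    BindingIsotherm, BindingMode, BindingPoint, MassBalanceError,
    bound_conc, free_conc, isotherm, linearity_test, scatchard, select_model,
)
from thtbind.simulate import GeneratorTruth, solve_equilibrium
from thtbind.studies import noisy_binding_series

from conftest import exact_binding_points


class TestConcentrations:
    def test_free_conc_beer_lambert(self):
        assert free_conc(0.316, 31600.0, 1.0) == pytest.approx(1.0e-5)
        assert free_conc(0.0) == 0.0

    def test_free_conc_path_length_proportionality(self):
        assert free_conc(0.316, 31600.0, 2.0) == pytest.approx(
            free_conc(0.316, 31600.0, 1.0) / 2)

    def test_bound_conc_mass_balance(self):
        assert bound_conc(3.2e-5, 1.0e-5) == pytest.approx(1.2e-5)
        assert bound_conc(3.2e-5, 1.6e-5) == 0.0  # Cf = C0/2: no binding

    def test_bound_conc_violation_raises(self):
        with pytest.raises(MassBalanceError):
            bound_conc(3.2e-5, 0.6 * 3.2e-5)

    def test_binding_point_enforces_mass_balance(self):
        with pytest.raises(MassBalanceError):
            BindingPoint(Cf=1e-5, Cb=1e-5, C0=4e-5, Cp=1e-4)


class TestIsotherm:
    MODE = BindingMode(Kb=1e4, n=0.1)

    def test_linear_limit(self):
        cf = 1e-6  # Kb*Cf = 0.01
        cb = isotherm(cf, 1.15e-4, [self.MODE])
        linear = 1.15e-4 * self.MODE.n * self.MODE.Kb * cf
        assert cb == pytest.approx(linear, rel=0.01)

    def test_saturation_limit(self):
        cf = 1.0  # Kb*Cf = 1e4
        cb = isotherm(cf, 1.15e-4, [self.MODE])
        assert cb / 1.15e-4 == pytest.approx(self.MODE.n, rel=1e-4)

    def test_closed_form_value(self):
        # Cp*n*KbCf/(1+KbCf) at KbCf=1 -> Cp*n/2
        assert isotherm(1e-4, 1.15e-4, [self.MODE]) == pytest.approx(5.75e-6)

    @settings(max_examples=50, derandomize=True)
    @given(kb=st.floats(1e2, 1e7), n=st.floats(1e-4, 1.0),
           cf1=st.floats(1e-8, 1e-3), cf2=st.floats(1e-8, 1e-3))
    def test_monotone_in_cf_and_kb(self, kb, n, cf1, cf2):
        lo, hi = sorted([cf1, cf2])
        m = BindingMode(kb, n)
        assert isotherm(lo, 1e-4, [m]) <= isotherm(hi, 1e-4, [m])
        m2 = BindingMode(kb * 2, n)
        assert isotherm(lo, 1e-4, [m]) <= isotherm(lo, 1e-4, [m2])


class TestScatchard:
    def test_one_mode_is_affine_with_slope_minus_kb(self, one_mode_truth):
        pts = exact_binding_points(one_mode_truth)
        x, y = scatchard(pts)
        slope, intercept = np.polyfit(x, y, 1)
        kb = one_mode_truth.modes[0].Kb
        n = one_mode_truth.modes[0].n
        assert slope == pytest.approx(-kb, rel=1e-9)
        # abscissa intercept at n*Cp
        assert intercept / kb == pytest.approx(n * one_mode_truth.Cp_M,
                                               rel=1e-9)

    def test_zero_cf_points_excluded_with_warning(self):
        pts = [BindingPoint(Cf=0.0, Cb=1e-5, C0=1e-5, Cp=1e-4),
               BindingPoint(Cf=1e-6, Cb=1e-6, C0=3e-6, Cp=1e-4)]
        with pytest.warns(UserWarning, match="excluded"):
            x, y = scatchard(pts)
        assert x.size == 1

    def test_two_mode_data_visibly_curved(self, two_mode_truth):
        pts = exact_binding_points(two_mode_truth)
        x, y = scatchard(pts)
        order = np.argsort(x)
        third = len(x) // 3
        s_lo = np.polyfit(x[order][:third + 1], y[order][:third + 1], 1)[0]
        s_hi = np.polyfit(x[order][-third - 1:], y[order][-third - 1:], 1)[0]
        assert abs(s_lo / s_hi) > 2


class TestLinearity:
    def test_exact_affine_accepted(self):
        x = np.linspace(1, 10, 10)
        y = 3 - 0.2 * x
        res = linearity_test(x, y)
        assert res.linear and res.p > 0.5

    def test_needs_six_points(self):
        with pytest.raises(ValueError):
            linearity_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_one_mode_noisy_mostly_accepted(self, one_mode_truth):
        accepted = 0
        for seed in range(100):
            pts = noisy_binding_series(one_mode_truth, seed, noise=0.005)
            x, y = scatchard(pts)
            accepted += linearity_test(x, y).linear
        assert accepted >= 95

    def test_two_mode_mostly_rejected(self, two_mode_truth):
        rejected = 0
        for seed in range(100):
            pts = noisy_binding_series(two_mode_truth, seed, noise=0.02)
            x, y = scatchard(pts)
            rejected += not linearity_test(x, y).linear
        assert rejected >= 90


class TestFitBinding:
    def test_noiseless_one_mode_exact_recovery(self, exact_one_mode_points):
        fit = BindingIsotherm(exact_one_mode_points).fit(1)
        assert fit.modes[0].Kb == pytest.approx(1e4, rel=1e-6)
        assert fit.modes[0].n == pytest.approx(0.05, rel=1e-6)

    def test_noiseless_two_mode_exact_recovery(self, two_mode_truth):
        pts = exact_binding_points(two_mode_truth)
        fit = BindingIsotherm(pts, weights="relative").fit(2)
        assert fit.modes[0].Kb == pytest.approx(1e6, rel=1e-4)
        assert fit.modes[1].Kb == pytest.approx(1e4, rel=1e-4)
        assert fit.modes[0].n == pytest.approx(5e-4, rel=1e-4)
        assert fit.modes[1].n == pytest.approx(0.05, rel=1e-4)

    def test_modes_sorted_by_descending_kb(self, two_mode_truth):
        pts = exact_binding_points(two_mode_truth)
        fit = BindingIsotherm(pts, weights="relative").fit(2)
        assert fit.modes[0].Kb > fit.modes[1].Kb

    def test_too_few_points_rejected(self, exact_one_mode_points):
        with pytest.raises(ValueError, match="at least 8"):
            BindingIsotherm(exact_one_mode_points[:6]).fit(2)

    def test_degenerate_two_mode_flagged(self, exact_one_mode_points):
        with pytest.warns(UserWarning, match="degenerate"):
            fit2 = BindingIsotherm(exact_one_mode_points,
                                   weights="relative").fit(2)
        assert fit2.degenerate


class TestSelectModel:
    def test_degenerate_fit2_chooses_one_mode(self, exact_one_mode_points):
        model = BindingIsotherm(exact_one_mode_points, weights="relative")
        fit1 = model.fit(1)
        with pytest.warns(UserWarning):
            fit2 = model.fit(2)
        sel = select_model(fit1, fit2)
        assert sel.n_modes == 1

    def test_two_mode_truth_selected(self, two_mode_truth):
        pts = noisy_binding_series(two_mode_truth, seed=5, noise=0.02)
        model = BindingIsotherm(pts, weights="relative")
        sel = select_model(model.fit(1, seed=5), model.fit(2, seed=5))
        assert sel.n_modes == 2
        assert sel.evidence["scatchard_linear"] is False


class TestBootstrap:
    def test_deterministic_under_seed(self, one_mode_truth):
        pts = noisy_binding_series(one_mode_truth, seed=3, noise=0.02)
        fit = BindingIsotherm(pts, weights="relative").fit(1, seed=3)
        ci_a = fit.bootstrap_ci(B=200, seed=11).conf_int
        ci_b = fit.bootstrap_ci(B=200, seed=11).conf_int
        assert ci_a == ci_b

    def test_near_noiseless_ci_is_tight(self, exact_one_mode_points):
        fit = BindingIsotherm(exact_one_mode_points).fit(1)
        ci = fit.bootstrap_ci(B=200, seed=0).conf_int
        lo, hi = ci["Kb_1"]
        assert (hi - lo) / 1e4 < 1e-4

    def test_requires_enough_replicates(self, exact_one_mode_points):
        fit = BindingIsotherm(exact_one_mode_points).fit(1)
        with pytest.raises(ValueError, match="200"):
            fit.bootstrap_ci(B=50)

    def test_coverage_of_true_kb(self, one_mode_truth):
        # 95% CIs should cover the true Kb in roughly 90-99% of datasets
        covered = 0
        n_data = 60
        for seed in range(n_data):
            pts = noisy_binding_series(one_mode_truth, seed, noise=0.02)
            fit = BindingIsotherm(pts, weights="relative").fit(
                1, n_restarts=2, seed=seed)
            lo, hi = fit.bootstrap_ci(B=200, seed=seed).conf_int["Kb_1"]
            covered += lo <= 1e4 <= hi
        assert 0.85 * n_data <= covered <= n_data


class TestEquilibriumConsistency:
    def test_fit_of_generated_data_recovers_truth(self):
        # generator and estimator are mutually consistent: fit(generate(x)) = x
        truth = GeneratorTruth(modes=(BindingMode(3e4, 0.02),))
        pts = exact_binding_points(truth)
        fit = BindingIsotherm(pts).fit(1)
        assert fit.modes[0].Kb == pytest.approx(3e4, rel=1e-6)
        assert fit.modes[0].n == pytest.approx(0.02, rel=1e-6)

    def test_accepted_points_satisfy_mass_balance(self, one_mode_truth):
        for p in exact_binding_points(one_mode_truth):
            assert abs(p.mass_balance_residual) < 1e-9

    def test_solver_limits(self):
        cf, cb = solve_equilibrium(1e-5, 1e-4, [])
        assert (cf, cb) == (5e-6, 0.0)
        # stoichiometric limit: huge Kb, excess sites -> all dye bound
        cf, cb = solve_equilibrium(1e-5, 1e-4, [BindingMode(1e12, 0.5)])
        assert cb == pytest.approx(1e-5, rel=1e-4)
        assert cf < 1e-9
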