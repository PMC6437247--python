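import dataclasses

import numpy as np
import pytest

from acekin.input_function import (
    AnalyticInputParams,
    InputFitError,
    InputFunctionError,
    MetaboliteCorrectionParams,
    apply_delay,
    apply_dispersion,
    estimate_delay,
    eval_analytic_input,
    fit_analytic_input,
    fit_dispersion,
    metabolite_correct,
)
from acekin.tac import SampledCurve, grid_1s


class TestMetaboliteCorrection:
    def test_no_correction_before_onset(self):
        t = grid_1s(120.0)
        cb = SampledCurve(t, np.full(t.size, 5.0))
        cp, cm = metabolite_correct(cb)
        before = t / 60.0 < 0.48
        np.testing.assert_array_equal(cp.y[before], 5.0)
        np.testing.assert_array_equal(cm.y[before], 0.0)

    def test_exponent_zero_at_onset(self):
        # at exactly t = onset the parent fraction is 1
        t = grid_1s(120.0)
        cb = SampledCurve(t, np.full(t.size, 10.0))
        cp, _ = metabolite_correct(cb)
        i = int(0.48 * 60)  # 28.8 s -> nearest grid points bracket the onset
        assert cp.y[i] == pytest.approx(10.0, rel=1e-3)

    def test_parent_fraction_ten_minutes_past_onset(self):
        # regression value: 8 SUV ten minutes past the onset -> 8 * exp(-1.04);
        # onset 0.8 min puts the evaluation time exactly on the 1-s grid
        t = grid_1s(660.0)
        cb = SampledCurve(t, np.full(t.size, 8.0))
        cp, _ = metabolite_correct(cb, MetaboliteCorrectionParams(rate=0.104, onset=0.8))
        i = int(10.8 * 60)
        assert cp.y[i] == pytest.approx(2.8276374556702413, rel=1e-12)

    def test_parent_never_exceeds_blood_and_metabolite_fraction_monotone(self, ysw_inputs):
        cp, cm = metabolite_correct(ysw_inputs.Cb)
        assert np.all(cp.y <= ysw_inputs.Cb.y + 1e-12)
        t_min = ysw_inputs.t / 60.0
        mask = (t_min >= 0.48) & (ysw_inputs.Cb.y > 1e-9)
        frac = cm.y[mask] / ysw_inputs.Cb.y[mask]
        assert np.all(np.diff(frac) >= -1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(InputFunctionError):
            MetaboliteCorrectionParams(rate=-0.1)


class TestDelay:
    def test_identical_curves_zero_delay(self, ysw_inputs):
        assert estimate_delay(ysw_inputs.Cb, ysw_inputs.Cb) == 0.0

    @pytest.mark.parametrize("shift", [3.0, -2.0])
    def test_constructed_shift_recovered(self, ysw_inputs, shift):
        local = apply_delay(ysw_inputs.Cb, shift)
        assert estimate_delay(ysw_inputs.Cb, local) == shift

    def test_flat_curve_raises(self):
        t = grid_1s(300.0)
        flat = SampledCurve(t, np.ones(t.size))
        with pytest.raises(InputFunctionError):
            estimate_delay(flat, flat)

    def test_zero_delay_is_identity_and_shift_moves_peak(self, ysw_inputs):
        same = apply_delay(ysw_inputs.Cb, 0.0)
        np.testing.assert_array_equal(same.y, ysw_inputs.Cb.y)
        shifted = apply_delay(ysw_inputs.Cb, 5.0)
        assert np.argmax(shifted.y) == np.argmax(ysw_inputs.Cb.y) + 5

    def test_delay_near_inverse(self, ysw_inputs):
        back = apply_delay(apply_delay(ysw_inputs.Cb, 5.0), -5.0)
        np.testing.assert_array_equal(back.y[:-5], ysw_inputs.Cb.y[:-5])


class TestDispersion:
    def test_tau_zero_is_identity(self, ysw_inputs):
        out = apply_dispersion(ysw_inputs.Cb, 0.0)
        np.testing.assert_array_equal(out.y, ysw_inputs.Cb.y)

    @pytest.mark.parametrize("tau", [2.0, 10.0, 25.0])
    def test_step_response_closed_form(self, tau):
        # constant input c disperses to c * (1 - exp(-(t + 1/2)/tau)) with the
        # cell-integrated kernel
        t = grid_1s(1800.0)
        c = 5.0
        out = apply_dispersion(SampledCurve(t, np.full(t.size, c)), tau)
        np.testing.assert_allclose(out.y, c * (1 - np.exp(-(t + 0.5) / tau)), atol=1e-9)

    def test_kernel_preserves_area_of_finite_pulse(self):
        t = grid_1s(1800.0)
        y = np.zeros(t.size)
        y[50:80] = 3.0
        out = apply_dispersion(SampledCurve(t, y), 15.0)
        assert np.sum(out.y) == pytest.approx(np.sum(y), rel=1e-9)

    def test_negative_tau_rejected(self, ysw_inputs):
        with pytest.raises(InputFunctionError):
            apply_dispersion(ysw_inputs.Cb, -1.0)

    def test_delay_and_dispersion_commute(self, ysw_inputs):
        a = apply_delay(apply_dispersion(ysw_inputs.Cb, 10.0), 5.0)
        b = apply_dispersion(apply_delay(ysw_inputs.Cb, 5.0), 10.0)
        np.testing.assert_allclose(a.y[10:], b.y[10:], atol=1e-9)


class TestFitDispersion:
    @pytest.mark.parametrize("tau", [5.0, 10.0, 25.0])
    def test_self_consistency_recovery(self, ysw_inputs, tau):
        local = apply_dispersion(ysw_inputs.Cb, tau)
        assert fit_dispersion(ysw_inputs.Cb, local) == pytest.approx(tau, abs=1.0)

    def test_identity_gives_zero(self, ysw_inputs):
        assert fit_dispersion(ysw_inputs.Cb, ysw_inputs.Cb) == pytest.approx(0.0, abs=0.5)

    def test_noisy_recovery_within_two_seconds(self, ysw_inputs):
        rng = np.random.default_rng(42)
        dispersed = apply_dispersion(ysw_inputs.Cb, 25.0)
        noisy = dispersed.copy_with(dispersed.y + rng.normal(0, 0.05, dispersed.y.size))
        assert fit_dispersion(ysw_inputs.Cb, noisy) == pytest.approx(25.0, abs=2.0)


class TestAnalyticInput:
    def test_rate_ordering_enforced(self):
        with pytest.raises(InputFunctionError):
            AnalyticInputParams(0.5, 100.0, 1.0, 1.0, 0.5, 4.0, 0.1)

    def test_zero_before_bolus_arrival(self):
        p = AnalyticInputParams(0.5, 100.0, 1.0, 1.0, 4.0, 0.5, 0.1)
        t = grid_1s(120.0)
        y = eval_analytic_input(p, t)
        assert np.all(y[t / 60.0 <= 0.5] == 0.0)

    def test_self_fit_recovers_parameters_within_one_percent(self):
        truth = AnalyticInputParams(0.5, 200.0, 4.0, 1.2, 4.0, 0.5, 0.22)
        t = grid_1s(1800.0)
        curve = SampledCurve(t, eval_analytic_input(truth, t))
        fitted = fit_analytic_input(curve)
        for f in dataclasses.fields(truth):
            got, want = getattr(fitted, f.name), getattr(truth, f.name)
            assert got == pytest.approx(want, rel=0.01), f.name

    def test_all_zero_curve_raises(self):
        t = grid_1s(600.0)
        with pytest.raises(InputFitError):
            fit_analytic_input(SampledCurve(t, np.zeros(t.size)))

    def test_fit_beats_single_exponential(self, ysw_inputs):
        # nested-model property: the tri-exponential RSS cannot exceed the
        # best single-exponential RSS on the same bolus curve
        from scipy.optimize import curve_fit

        y = ysw_inputs.Cp.y
        t = ysw_inputs.t / 60.0
        fitted = fit_analytic_input(ysw_inputs.Cp)
        rss_tri = float(np.sum((eval_analytic_input(fitted, ysw_inputs.t) - y) ** 2))
        popt, _ = curve_fit(lambda tt, a, l: a * np.exp(-l * tt), t, y, p0=[10.0, 0.5])
        rss_mono = float(np.sum((popt[0] * np.exp(-popt[1] * t) - y) ** 2))
        assert rss_tri <= rss_mono


class TestInputFunctionSet:
    def test_cm_must_equal_cb_minus_cp(self):
        from acekin.input_function import InputFunctionSet

        t = grid_1s(60.0)
        one = np.ones(t.size)
        with pytest.raises(InputFunctionError):
            InputFunctionSet(
                Cb=SampledCurve(t, 2 * one),
                Cp=SampledCurve(t, one),
                Cm=SampledCurve(t, 0.5 * one),
            )
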