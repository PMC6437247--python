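import numpy as np
import pytest
from scipy.signal import fftconvolve

import acekin as ak
from acekin.models import (
    MODEL_IDS,
    get_model_spec,
    monoexp_index,
    patlak,
    simulate_tissue,
    total_signal,
)
from acekin.tac import SampledCurve, TimeActivityCurve, default_schedule, grid_1s

from conftest import bolus_inputs


class TestModelBank:
    def test_all_ten_models_defined(self):
        assert MODEL_IDS == tuple(range(1, 11))

    @pytest.mark.parametrize(
        "mid,n_tissue,params",
        [
            (1, 1, ("K1", "k2", "vb")),
            (2, 2, ("K1", "k2", "k3", "k4", "vb")),
            (7, 3, ("K1", "k2", "k3", "vb")),  # tied oxidative rate counted once
            (10, 3, ("K1", "k2", "k3", "k4", "k5", "vb")),
        ],
    )
    def test_spec_structure(self, mid, n_tissue, params):
        spec = get_model_spec(mid)
        assert spec.n_tissue == n_tissue
        assert spec.free_params == params

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            get_model_spec(11)

    def test_model2_template_matches_reversible_two_tissue_equations(self):
        # dC1 = K1 Cp - (k2+k3) C1 + k4 C2 ; dC2 = k3 C1 - k4 C2
        spec = get_model_spec(2)
        A, bp, bm = spec.system({"K1": 0.07, "k2": 0.1, "k3": 0.05, "k4": 0.02, "vb": 0.1})
        np.testing.assert_allclose(A, [[-0.15, 0.02], [0.05, -0.02]])
        np.testing.assert_allclose(bp, [0.07, 0.0])
        assert not np.any(bm)


class TestSimulate:
    def test_zero_uptake_gives_blood_only_signal(self, ysw_inputs):
        cc = simulate_tissue(get_model_spec(1), {"K1": 0.0, "k2": 0.14, "vb": 0.3}, ysw_inputs)
        assert np.all(cc.C[0].y == 0.0)
        np.testing.assert_allclose(cc.Ctot.y, 0.3 * ysw_inputs.Cb.y, atol=1e-12)

    def test_model1_matches_analytic_convolution(self, ysw_inputs):
        # independent oracle: fine-grid FFT convolution K1 e^(-k2 t) (*) Cp
        K1, k2 = 0.07, 0.14
        cc = simulate_tissue(get_model_spec(1), {"K1": K1, "k2": k2, "vb": 0.0}, ysw_inputs)
        dt = 0.01
        tf = np.arange(0.0, 1800.0 + dt / 2, dt)
        cp = np.interp(tf, ysw_inputs.t, ysw_inputs.Cp.y)
        kern = K1 * np.exp(-k2 * tf / 60.0) / 60.0
        oracle = np.interp(ysw_inputs.t, tf, fftconvolve(cp, kern)[: tf.size] * dt)
        rel = np.max(np.abs(cc.C[0].y - oracle)) / np.max(oracle)
        assert rel < 1e-3

    @pytest.mark.parametrize(
        "full_id,full_params,reduced_id,reduced_params",
        [
            (2, {"K1": 0.07, "k2": 0.14, "k3": 0.0, "k4": 0.0, "vb": 0.1},
             1, {"K1": 0.07, "k2": 0.14, "vb": 0.1}),
            (5, {"K1": 0.07, "k2": 0.0, "k3": 0.3, "k4": 0.14, "k5": 0.0, "vb": 0.1},
             7, {"K1": 0.07, "k2": 0.3, "k3": 0.14, "vb": 0.1}),
            (10, {"K1": 0.07, "k2": 0.14, "k3": 0.05, "k4": 0.0, "k5": 0.0, "vb": 0.1},
             4, {"K1": 0.07, "k2": 0.14, "k3": 0.05, "vb": 0.1}),
        ],
    )
    def test_nested_model_reductions(self, ysw_inputs, full_id, full_params,
                                     reduced_id, reduced_params):
        full = simulate_tissue(get_model_spec(full_id), full_params, ysw_inputs).Ctot.y
        reduced = simulate_tissue(get_model_spec(reduced_id), reduced_params, ysw_inputs).Ctot.y
        np.testing.assert_allclose(full, reduced, atol=1e-12)

    def test_model7_closed_storage_pathway(self, ysw_inputs):
        cc = simulate_tissue(get_model_spec(7), {"K1": 0.07, "k2": 0.3, "k3": 0.0, "vb": 0.1},
                             ysw_inputs)
        assert np.all(cc.C[1].y == 0.0)

    def test_mass_balance_without_elimination(self, ysw_inputs):
        # with no elimination, tissue content equals K1 * cumulative Cp intake
        cc = simulate_tissue(get_model_spec(4), {"K1": 0.07, "k2": 0.0, "k3": 0.05, "vb": 0.0},
                             ysw_inputs)
        total = cc.C[0].y[-1] + cc.C[1].y[-1]
        intake = 0.07 * np.trapezoid(ysw_inputs.Cp.y, ysw_inputs.t / 60.0)
        assert total == pytest.approx(intake, rel=1e-3)

    def test_nonnegative_compartments_all_models(self, ysw_inputs, ysw_preset):
        for mid in MODEL_IDS:
            cc = simulate_tissue(get_model_spec(mid), ysw_preset.truth[mid], ysw_inputs)
            for c in cc.C:
                assert np.min(c.y) >= -1e-12, f"model {mid}"

    def test_linearity_in_input_amplitude(self, ysw_inputs):
        from acekin.synthetic import perturb_aif

        spec = get_model_spec(7)
        params = {"K1": 0.07, "k2": 0.3, "k3": 0.14, "vb": 0.1}
        base = simulate_tissue(spec, params, ysw_inputs).Ctot.y
        doubled = simulate_tissue(spec, params, perturb_aif(ysw_inputs, 2.0)).Ctot.y
        np.testing.assert_allclose(doubled, 2.0 * base, rtol=1e-9)

    def test_missing_parameter_rejected(self, ysw_inputs):
        with pytest.raises(ValueError):
            simulate_tissue(get_model_spec(1), {"K1": 0.07, "vb": 0.1}, ysw_inputs)


class TestTotalSignal:
    def test_vb_one_returns_blood(self, ysw_inputs):
        t = ysw_inputs.t
        ci = [SampledCurve(t, np.ones(t.size))]
        out = total_signal(ci, 1.0, ysw_inputs.Cb)
        np.testing.assert_array_equal(out.y, ysw_inputs.Cb.y)

    def test_vb_zero_returns_tissue_sum(self, ysw_inputs):
        t = ysw_inputs.t
        ci = [SampledCurve(t, np.full(t.size, 0.3)), SampledCurve(t, np.full(t.size, 0.2))]
        out = total_signal(ci, 0.0, ysw_inputs.Cb)
        np.testing.assert_allclose(out.y, 0.5)

    def test_convexity_fixed_point(self, ysw_inputs):
        ci = [ysw_inputs.Cb]
        out = total_signal(ci, 0.5, ysw_inputs.Cb)
        np.testing.assert_allclose(out.y, ysw_inputs.Cb.y)


class TestMonoexp:
    def test_exact_exponential_recovered(self, schedule):
        t_min = schedule.mid_times / 60.0
        tac = TimeActivityCurve(schedule, 2.0 * np.exp(-0.5 * t_min))
        res = monoexp_index(tac)
        assert res.Kmono == pytest.approx(0.5, rel=1e-6)
        assert res.amplitude == pytest.approx(2.0, rel=1e-6)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_curve_zero_decay(self, schedule):
        res = monoexp_index(TimeActivityCurve(schedule, np.full(40, 1.7)))
        assert res.Kmono == 0.0

    def test_noisy_recovery_within_ten_percent(self, schedule):
        rng = np.random.default_rng(7)
        t_min = schedule.mid_times / 60.0
        clean = 2.0 * np.exp(-0.5 * t_min)
        tac = TimeActivityCurve(schedule, clean + rng.normal(0, 0.02, 40))
        res = monoexp_index(tac)
        assert res.Kmono == pytest.approx(0.5, rel=0.10)

    def test_too_few_points_raises(self, schedule):
        tac = TimeActivityCurve(schedule, np.ones(40))
        with pytest.raises(ValueError):
            monoexp_index(tac, window=(1.5, 1.6))


class TestPatlak:
    def test_irreversible_trap_positive_slope(self, clean_inputs):
        cc = simulate_tissue(get_model_spec(4), {"K1": 0.07, "k2": 0.5, "k3": 0.05, "vb": 0.0},
                             clean_inputs)
        res = patlak(cc.Ctot, clean_inputs.Cp, 15.0)
        assert res.Ki > 0
        assert res.r2 > 0.95

    def test_reversible_model_near_zero_slope(self):
        # slow-tail input so the one-tissue model reaches equilibrium
        ifs = bolus_inputs(l3=0.05)
        slope_rev = patlak(
            simulate_tissue(get_model_spec(1), {"K1": 0.07, "k2": 0.5, "vb": 0.0}, ifs).Ctot,
            ifs.Cp, 15.0,
        ).Ki
        slope_trap = patlak(
            simulate_tissue(get_model_spec(4), {"K1": 0.07, "k2": 0.5, "k3": 0.05, "vb": 0.0},
                            ifs).Ctot,
            ifs.Cp, 15.0,
        ).Ki
        assert abs(slope_rev) < 0.05 * slope_trap

    def test_blood_only_limit_recovers_vb(self, clean_inputs):
        vb = 0.2
        tissue = SampledCurve(clean_inputs.t, vb * clean_inputs.Cp.y)
        res = patlak(tissue, clean_inputs.Cp, 10.0)
        assert res.Ki == pytest.approx(0.0, abs=1e-9)
        assert res.intercept == pytest.approx(vb, abs=1e-9)

    def test_degenerate_abscissa_raises(self):
        t = grid_1s(1800.0)
        flat = SampledCurve(t, np.ones(t.size))
        with pytest.raises(ValueError):
            patlak(flat, SampledCurve(t, np.zeros(t.size)), 10.0)
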