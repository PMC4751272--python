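import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cablenet.membrane import (CalciumParams, CalciumState, HHState,
                               MechanismSpec, HHRegionParams, PumpParams,
                               TABLE_NETWORK_SPEC, VDCCParams,
                               calibrate_leak_reversal, ghk_current_density,
                               hh_current_density, hh_gate_step, hh_rates,
                               hh_steady_state, pump_flux,
                               vdcc_current_density, vdcc_gate_steady_state,
                               CalciumModel, FARADAY)


class TestHHRates:
    def test_resting_steady_states_match_classical_values(self):
        n, m, h = hh_steady_state(-65.0)
        assert n == pytest.approx(0.3177, abs=5e-5)
        assert m == pytest.approx(0.0529, abs=5e-5)
        assert h == pytest.approx(0.5961, abs=5e-5)

    def test_alpha_n_singularity_returns_limit(self):
        # alpha_n is singular 10 mV above rest; the limit is 0.1 ms^-1
        a_n = hh_rates(-55.0)[0]
        assert np.isfinite(a_n)
        assert a_n == pytest.approx(0.1, rel=1e-6)

    def test_alpha_m_singularity_returns_limit(self):
        a_m = hh_rates(-40.0)[2]
        assert np.isfinite(a_m)
        assert a_m == pytest.approx(1.0, rel=1e-6)

    def test_depolarized_asymptotics(self):
        n, m, h = hh_steady_state(200.0)
        assert m > 0.999
        assert h < 1e-3

    def test_vectorised_evaluation(self):
        V = np.linspace(-100, 60, 33)
        rates = hh_rates(V)
        assert all(r.shape == V.shape for r in rates)
        assert all(np.all(r >= 0) for r in rates)


class TestGateStep:
    def test_resting_state_is_fixed_point(self):
        n, m, h = hh_steady_state(-65.0)
        st = HHState(np.array([n]), np.array([m]), np.array([h]))
        out = hh_gate_step(st, -65.0, dt_ms=0.01)
        assert abs(out.n[0] - n) < 1e-12
        assert abs(out.m[0] - m) < 1e-12
        assert abs(out.h[0] - h) < 1e-12

    def test_gates_stay_in_unit_interval(self):
        st = HHState(np.array([0.99]), np.array([0.99]), np.array([0.01]))
        for V in (-120.0, 80.0):
            out = st
            for _ in range(200):
                out = hh_gate_step(out, V, dt_ms=0.05)
            for g in (out.n, out.m, out.h):
                assert np.all((g >= 0) & (g <= 1))

    def test_first_order_convergence_against_ode_oracle(self):
        # explicit stepping halving dt halves the error w.r.t. an
        # adaptive high-accuracy integration of the same gate ODEs
        V, c_T = -40.0, 3.21

        def rhs(t, y):
            a_n, b_n, a_m, b_m, a_h, b_h = hh_rates(V)
            return [c_T * (a_n * (1 - y[0]) - b_n * y[0]),
                    c_T * (a_m * (1 - y[1]) - b_m * y[1]),
                    c_T * (a_h * (1 - y[2]) - b_h * y[2])]

        y0 = list(hh_steady_state(-65.0))
        ref = solve_ivp(rhs, (0, 2.0), y0, rtol=1e-10, atol=1e-12).y[:, -1]
        errs = []
        for dt in (0.02, 0.01):
            st = HHState(*[np.array([v]) for v in y0])
            for _ in range(int(round(2.0 / dt))):
                st = hh_gate_step(st, V, dt_ms=dt, c_T=c_T)
            errs.append(abs(st.m[0] - ref[1]))
        assert errs[1] < 0.7 * errs[0]  # O(dt)

    def test_temperature_factor_accelerates_relaxation(self):
        # time to cover half the distance to equilibrium scales ~1/c_T
        V = -40.0
        m_inf = hh_steady_state(V)[1]
        m0 = hh_steady_state(-65.0)[1]
        half = m0 + 0.5 * (m_inf - m0)
        times = {}
        for c_T in (1.0, 3.21):
            st = HHState(np.array([hh_steady_state(-65.0)[0]]),
                         np.array([m0]), np.array([hh_steady_state(-65.0)[2]]))
            t, dt = 0.0, 0.001
            while st.m[0] < half:
                st = hh_gate_step(st, V, dt_ms=dt, c_T=c_T)
                t += dt
            times[c_T] = t
        assert times[1.0] / times[3.21] == pytest.approx(3.21, rel=0.02)


class TestCurrentDensity:
    def test_axonal_rest_current_reference_value(self):
        n, m, h = hh_steady_state(-65.0)
        st = HHState(np.array(n), np.array(m), np.array(h))
        i = hh_current_density(st, -0.065, TABLE_NETWORK_SPEC, "axon")
        # 400·n∞⁴·0.025 + 30000·m∞³h∞·(−0.125), times c_T
        assert i / TABLE_NETWORK_SPEC.c_T == pytest.approx(-0.2297, abs=2e-4)

    def test_potassium_term_vanishes_at_its_reversal(self):
        st = HHState(np.array(0.5), np.array(0.0), np.array(0.5))
        i = hh_current_density(st, TABLE_NETWORK_SPEC.E_K,
                               TABLE_NETWORK_SPEC, "soma")
        assert i == pytest.approx(0.0)

    def test_sodium_term_linear_in_conductance(self):
        n, m, h = hh_steady_state(-50.0)
        st = HHState(np.array(n), np.array(m), np.array(h))
        base = MechanismSpec(regions={"soma": HHRegionParams(0.0, 1500.0, 1.0)},
                             E_l={"soma": -0.06})
        double = MechanismSpec(regions={"soma": HHRegionParams(0.0, 3000.0, 1.0)},
                               E_l={"soma": -0.06})
        i1 = hh_current_density(st, -0.05, base, "soma")
        i2 = hh_current_density(st, -0.05, double, "soma")
        assert i2 == pytest.approx(2 * i1, rel=1e-12)


class TestLeakCalibration:
    @pytest.mark.parametrize("region,expected", [
        ("axon", -0.066148458),
        ("soma", -0.030654022),
        ("dendrite", -0.057803624),
    ])
    def test_reference_reversal_potentials(self, region, expected):
        E_l = calibrate_leak_reversal(TABLE_NETWORK_SPEC, region)
        assert abs(E_l - expected) <= 2e-6

    def test_pure_leak_membrane_rests_at_vr(self):
        spec = MechanismSpec(regions={"soma": HHRegionParams(0.0, 0.0, 1.0)})
        assert calibrate_leak_reversal(spec, "soma") == pytest.approx(-0.065)

    def test_zero_leak_conductance_rejected(self):
        spec = MechanismSpec(regions={"soma": HHRegionParams(100.0, 100.0, 0.0)})
        with pytest.raises(ValueError):
            calibrate_leak_reversal(spec, "soma")

    def test_calibration_independent_of_temperature_factor(self):
        warm = MechanismSpec(regions=dict(TABLE_NETWORK_SPEC.regions), c_T=1.0)
        assert calibrate_leak_reversal(warm, "axon") == pytest.approx(
            calibrate_leak_reversal(TABLE_NETWORK_SPEC, "axon"), abs=1e-15)


class TestVDCC:
    def test_gate_steady_state_monotone_in_voltage(self):
        V = np.linspace(-0.09, 0.05, 50)
        m_inf, _ = vdcc_gate_steady_state(V)
        assert np.all(np.diff(m_inf) > 0)

    def test_rest_is_a_fixed_point_of_the_model(self):
        model = CalciumModel(CalciumParams(), ["soma", "dendrite-basal"],
                             V_rest=-0.065)
        flux0 = model.membrane_flux(np.array([-0.065, -0.065])).copy()
        for _ in range(100):
            model.prepare(np.array([-0.065, -0.065]), 1e-4)
        flux1 = model.membrane_flux(np.array([-0.065, -0.065]))
        np.testing.assert_allclose(flux0, 0.0, atol=1e-18)
        np.testing.assert_allclose(flux1, 0.0, atol=1e-18)

    def test_depolarization_step_gives_inward_calcium_current(self):
        model = CalciumModel(CalciumParams(), ["soma"], V_rest=-0.065)
        V = np.array([0.0])  # strong depolarization
        for _ in range(200):
            model.prepare(V, 1e-4)
        i = model.vdcc_charge_current(V)
        assert i[0] < 0  # inward in the outward-positive convention

    def test_ghk_singularity_at_zero_voltage(self):
        i0 = ghk_current_density(0.0, 5e-5, 2.0, 3.8e-8)
        lim = 3.8e-8 * 2 * FARADAY * (5e-5 - 2.0)
        assert i0 == pytest.approx(lim, rel=1e-6)


class TestPumps:
    def test_zero_concentration_gives_zero_flux(self):
        assert pump_flux("NCX", 0.0) == 0.0
        assert pump_flux("PMCA", 0.0) == 0.0

    def test_half_saturation_points(self):
        p = PumpParams()
        assert pump_flux("NCX", p.ncx_K, p) == pytest.approx(p.ncx_vmax / 2)
        assert pump_flux("PMCA", p.pmca_K, p) == pytest.approx(p.pmca_vmax / 2)

    def test_unknown_pump_rejected(self):
        with pytest.raises(ValueError):
            pump_flux("SERCA", 1e-4)

    def test_leak_balances_pumps_and_vdcc_at_rest(self):
        params = CalciumParams()
        model = CalciumModel(params, ["dendrite-basal"], V_rest=-0.065)
        total = model.membrane_flux(np.array([-0.065]))
        assert abs(total[0]) < 1e-18
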