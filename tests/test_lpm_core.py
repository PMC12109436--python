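"""Pump source, network equations, simulation and resistance tuning."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fontanjet import (PumpSettings, SimulationConfig, cycle_average,
                       get_case, lpm_derivatives, pump_flow, simulate,
                       tune_resistances)
from fontanjet.errors import (ConvergenceError, InsufficientWindowError,
                              InvalidParameterError, InvalidTargetError,
                              NumericStateError)
from fontanjet.lpm_core import (STATE_LAYOUT, WindkesselCompartment,
                                measured_splits)
from fontanjet.waveform import WaveformRecord


class TestPumpFlow:
    def test_cycle_average_is_hr_times_sv(self):
        """80 bpm x 30 mL integrates to 2.4 L/min over one period."""
        pump = PumpSettings(heart_rate=80.0, stroke_volume=30.0)
        t = np.linspace(0.0, pump.period, 200001)
        mean = np.trapezoid(pump_flow(t, pump), t) / pump.period
        assert mean == pytest.approx(2.4, rel=1e-6)

    def test_zero_stroke_volume_gives_zero_flow(self):
        pump = PumpSettings(stroke_volume=0.0)
        t = np.linspace(0.0, 3.0, 1000)
        assert np.all(pump_flow(t, pump) == 0.0)

    def test_peak_matches_half_sine_closed_form(self):
        """Dense maximization of the waveform equals pi*SV/(2*T_ej)."""
        pump = PumpSettings(heart_rate=80.0, stroke_volume=30.0,
                            ejection_fraction_of_cycle=0.3)
        t_ej = 0.3 * pump.period
        expected_peak = np.pi * 30.0 / (2.0 * t_ej) * 0.06  # L/min
        t = np.linspace(0.0, pump.period, 500001)
        assert pump_flow(t, pump).max() == pytest.approx(expected_peak, rel=1e-6)

    def test_periodicity(self):
        pump = PumpSettings()
        t = np.linspace(0.0, pump.period, 997)
        np.testing.assert_allclose(pump_flow(t, pump),
                                   pump_flow(t + 7 * pump.period, pump),
                                   atol=1e-9)

    def test_invalid_heart_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            PumpSettings(heart_rate=0.0)


class TestDerivatives:
    def test_equilibrium_all_derivatives_zero(self, params):
        state = np.full(5, params.venous_reference_pressure)
        dydt = lpm_derivatives(state, 0.0, params, {"pump": 0.0})
        np.testing.assert_allclose(dydt, 0.0, atol=1e-12)

    def test_compliance_budget_closes(self, params, rng):
        """Sum of C dP/dt equals external inflow minus outflow to reference.

        Independent oracle: explicit summation of every branch flow
        (storage in the chambers is the only place volume can go; the
        junction node stores nothing).
        """
        from fontanjet.lpm_core import _Coefficients
        c = _Coefficients.from_params(params)
        caps = np.array([c.c_a, c.c_up, c.c_low, c.c_rpa, c.c_lpa])
        for _ in range(25):
            state = rng.uniform(3.0, 120.0, 5)
            q_pump = float(rng.uniform(0.0, 5.0))
            q_inj = float(rng.uniform(0.0, 1.2))
            dydt = lpm_derivatives(state, 0.3, params,
                                   {"pump": q_pump, "injection": q_inj})
            stored = np.sum(caps * dydt) * 60.0 / 1000.0  # mL/mmHg*mmHg/s -> L/min
            out = ((state[3] - c.p_ref) / c.r_drain
                   + (state[4] - c.p_ref) / c.r_drain)
            assert stored == pytest.approx(q_pump + q_inj - out, abs=1e-9)

    def test_constant_inflow_reaches_ohmic_steady_state(self, params):
        """With a constant pump the chain settles to P = P_ref + Q*R drops."""
        q = 2.4
        fun = lambda t, y: lpm_derivatives(y, t, params, {"pump": q})
        y0 = np.full(5, params.venous_reference_pressure)
        sol = solve_ivp(fun, (0.0, 400.0), y0, method="LSODA", rtol=1e-10,
                        atol=1e-12)
        p_a, p_up, p_low, p_rpa, p_lpa = sol.y[:, -1]
        pl = params.plumbing
        # pulmonary chambers: half of CO each through the drain line
        expected_ppa = params.venous_reference_pressure + 0.5 * q * pl.drain_resistance
        assert p_rpa == pytest.approx(expected_ppa, rel=1e-3)
        assert p_lpa == pytest.approx(expected_ppa, rel=1e-3)
        # upper branch carries the systemic split through its arterial R
        r_up = params.compartment("upper_systemic").resistance
        q_up = (p_a - p_up) / r_up
        assert q_up == pytest.approx(q * params.systemic_split_target, rel=2e-3)

    def test_non_finite_state_rejected(self, params):
        state = np.array([np.nan, 10.0, 10.0, 7.0, 7.0])
        with pytest.raises(NumericStateError):
            lpm_derivatives(state, 0.0, params, {})


class TestSimulate:
    def test_mass_conservation_no_injection(self, baseline_record, settle_window):
        q_sys = (cycle_average(baseline_record, "q_upper", settle_window)
                 + cycle_average(baseline_record, "q_lower", settle_window))
        q_pul = (cycle_average(baseline_record, "q_rpa", settle_window)
                 + cycle_average(baseline_record, "q_lpa", settle_window))
        assert abs(q_sys - q_pul) / q_sys < 0.01

    def test_cardiac_output_target(self, baseline_record, settle_window):
        q_sys = (cycle_average(baseline_record, "q_upper", settle_window)
                 + cycle_average(baseline_record, "q_lower", settle_window))
        assert q_sys == pytest.approx(2.4, rel=0.02)

    def test_injection_flow_bookkeeping(self, params):
        """During a 0.6 L/min continuous injection the pulmonary flows sum
        to CO + 0.6 at periodic steady state."""
        proto = get_case(14, start_time=12.0)  # 10 cc/s x 150 cc -> 15 s on
        cfg = SimulationConfig(duration=27.0)
        rec = simulate(params, proto, cfg)
        window = (19.5, 27.0)  # last 10 cycles of the active window
        q_pul = (cycle_average(rec, "q_rpa", window)
                 + cycle_average(rec, "q_lpa", window))
        assert q_pul == pytest.approx(2.4 + 0.6, rel=0.02)

    def test_insufficient_settle_span_raises(self, params):
        proto = get_case(12, start_time=2.0)  # injection before settling
        with pytest.raises(ConvergenceError):
            simulate(params, proto, SimulationConfig(duration=20.0))

    def test_duration_must_cover_settle_cycles(self, params):
        with pytest.raises(InvalidParameterError):
            simulate(params, None, SimulationConfig(duration=2.0, settle_cycles=10))


class TestTuning:
    def test_default_targets_within_one_percent(self, params, baseline_record,
                                                settle_window):
        sys_split, pul_split = measured_splits(baseline_record, settle_window)
        assert abs(sys_split - 0.30) < 0.01
        assert abs(pul_split - 0.50) < 0.01

    def test_idempotent_on_tuned_parameters(self, params):
        retuned = tune_resistances(params)
        for name in ("upper_systemic", "lower_systemic", "rpa", "lpa"):
            r0 = params.compartment(name).resistance
            r1 = retuned.compartment(name).resistance
            assert abs(r1 - r0) / r0 < 1e-3

    def test_detuned_converges_to_targets(self, params):
        detuned = (params.with_resistance("upper_systemic", 60.0)
                   .with_resistance("rpa", 11.0))
        tuned = tune_resistances(detuned)
        cfg = SimulationConfig(duration=14.0, settle_cycles=8)
        rec = simulate(tuned, None, cfg)
        sys_split, pul_split = measured_splits(rec, (6.0, 14.0))
        assert abs(sys_split - 0.30) < 0.01
        assert abs(pul_split - 0.50) < 0.01

    def test_symmetric_target_gives_equal_resistances(self, params):
        from dataclasses import replace
        comps = tuple(replace(c, compliance=30.0) for c in params.compartments)
        sym = replace(params, compartments=comps, systemic_split_target=0.5)
        detuned = sym.with_resistance("upper_systemic", 90.0)
        tuned = tune_resistances(detuned)
        r_up = tuned.compartment("upper_systemic").resistance
        r_low = tuned.compartment("lower_systemic").resistance
        # equal split through identical plumbing requires equal total path R
        assert r_up == pytest.approx(r_low, rel=0.02)

    def test_nondefault_target_achieved(self, params):
        from dataclasses import replace
        goal = replace(params, systemic_split_target=0.70)
        tuned = tune_resistances(goal)
        cfg = SimulationConfig(duration=14.0, settle_cycles=8)
        sys_split, _ = measured_splits(simulate(tuned, None, cfg), (6.0, 14.0))
        assert abs(sys_split - 0.70) < 0.01

    def test_invalid_target_rejected(self, params):
        from dataclasses import replace
        with pytest.raises(InvalidTargetError):
            replace(params, systemic_split_target=1.2)

    def test_monotonicity_in_upper_resistance(self, params):
        """Raising the upper-systemic resistance strictly lowers mean Q_upper."""
        cfg = SimulationConfig(duration=12.0, settle_cycles=8)
        window = (6.0, 12.0)
        means = []
        r0 = params.compartment("upper_systemic").resistance
        for scale in (0.8, 1.0, 1.3):
            rec = simulate(params.with_resistance("upper_systemic", r0 * scale),
                           None, cfg)
            means.append(cycle_average(rec, "q_upper", window))
        assert means[0] > means[1] > means[2]


class TestCycleAverage:
    def _record(self, t, x):
        return WaveformRecord(t, {"q_rpa": x}, 1.0 / (t[1] - t[0]),
                              {"heart_rate": 80.0})

    def test_constant_channel(self):
        t = np.arange(0.0, 10.0, 0.01)
        rec = self._record(t, np.full_like(t, 1.7))
        assert cycle_average(rec, "q_rpa", (0.0, 9.0)) == pytest.approx(1.7)

    def test_heart_frequency_sinusoid_averages_to_zero(self):
        t = np.arange(0.0, 9.0, 0.01)
        x = np.sin(2 * np.pi * t / 0.75)  # 80 bpm fundamental
        rec = self._record(t, x)
        # 8 whole cycles fit in (0, 6.1); partial tail is truncated
        assert cycle_average(rec, "q_rpa", (0.0, 6.1)) == pytest.approx(0.0, abs=1e-3)

    def test_pump_channel_average_equals_co(self, params):
        pump = params.pump
        t = np.arange(0.0, 3.0, 0.001)
        rec = WaveformRecord(t, {"q_pump": pump_flow(t, pump)}, 1000.0,
                             {"heart_rate": pump.heart_rate})
        got = cycle_average(rec, "q_pump", (0.0, pump.period))
        assert got == pytest.approx(pump.cardiac_output, rel=1e-3)

    def test_window_shorter_than_cycle_raises(self):
        t = np.arange(0.0, 10.0, 0.01)
        rec = self._record(t, np.ones_like(t))
        with pytest.raises(InsufficientWindowError):
            cycle_average(rec, "q_rpa", (0.0, 0.5))


class TestValidation:
    def test_negative_resistance_rejected(self):
        with pytest.raises(InvalidParameterError):
            WindkesselCompartment("rpa", -1.0, 5.0)

    def test_unknown_compartment_name_rejected(self):
        with pytest.raises(InvalidParameterError):
            WindkesselCompartment("coronary", 1.0, 5.0)

    def test_state_layout_documented(self):
        assert STATE_LAYOUT == ("p_aortic", "p_upper", "p_lower",
                                "p_rpa", "p_lpa")
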