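"""Step-response metrics against first-order closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fontanjet import (fall_metrics, pulsed_summary, relaxation_time,
                       rise_metrics)
from fontanjet.errors import (EmptyInputError, MalformedSegmentError,
                              NoResponseError)
from fontanjet.jet_characterization import JetResponseMetrics, combine

LN9 = np.log(9.0)
FS = 100.0


def first_order_rise(tau, amplitude=1.0, baseline=0.0, span=None, fs=FS):
    span = span or 30 * tau
    t = np.arange(0.0, span, 1.0 / fs)
    return t, baseline + amplitude * (1.0 - np.exp(-t / tau))


def first_order_fall(tau, amplitude=1.0, baseline=0.0, span=None, fs=FS):
    span = span or 30 * tau
    t = np.arange(0.0, span, 1.0 / fs)
    return t, baseline + amplitude * np.exp(-t / tau)


class TestRiseMetrics:
    @pytest.mark.parametrize("tau", [0.1, 0.23, 0.5])
    def test_rise_time_is_tau_ln9(self, tau):
        t, y = first_order_rise(tau)
        m = rise_metrics(t, y, 0.0)
        assert m.rise_time == pytest.approx(tau * LN9, abs=2.0 / FS)

    def test_settling_time_is_tau_ln50(self):
        tau = 0.5
        t, y = first_order_rise(tau, span=10 * tau)
        m = rise_metrics(t, y, 0.0)
        assert m.settling_time == pytest.approx(tau * np.log(50.0), abs=2.0 / FS)

    def test_monotone_saturating_step_has_zero_overshoot(self):
        t = np.arange(0.0, 10.0, 1.0 / FS)
        y = np.minimum(t / 2.0, 1.0)  # ramps, then holds exactly
        m = rise_metrics(t, y, 0.0)
        assert m.overshoot_pct == 0.0
        assert m.undershoot_pct == 0.0

    def test_overshoot_of_damped_oscillation(self):
        """Underdamped second-order step: overshoot matches exp(-pi*z/sqrt(1-z^2))."""
        z, wn = 0.4, 8.0
        t = np.arange(0.0, 12.0, 1.0 / FS)
        wd = wn * np.sqrt(1 - z ** 2)
        y = 1 - np.exp(-z * wn * t) * (np.cos(wd * t) + z / np.sqrt(1 - z ** 2)
                                       * np.sin(wd * t))
        m = rise_metrics(t, y, 0.0)
        expected = 100.0 * np.exp(-np.pi * z / np.sqrt(1 - z ** 2))
        assert m.overshoot_pct == pytest.approx(expected, abs=1.0)

    def test_no_response_raises(self):
        t = np.arange(0.0, 5.0, 1.0 / FS)
        with pytest.raises(NoResponseError):
            rise_metrics(t, np.full_like(t, 1.2), 1.3)


class TestFallMetrics:
    @pytest.mark.parametrize("tau", [0.1, 0.3])
    def test_fall_time_is_tau_ln9(self, tau):
        t, y = first_order_fall(tau, amplitude=0.8, baseline=1.2)
        m = fall_metrics(t, y, 1.2, 2.0)
        assert m.fall_time == pytest.approx(tau * LN9, abs=2.0 / FS)

    def test_symmetric_shapes_give_equal_times(self):
        tau = 0.25
        t, yr = first_order_rise(tau)
        _, yf = first_order_fall(tau)
        rise = rise_metrics(t, yr, 0.0)
        fall = fall_metrics(t, yf, 0.0, 1.0)
        assert fall.fall_time == pytest.approx(rise.rise_time, abs=1.0 / FS)

    def test_never_decaying_segment_raises(self):
        t = np.arange(0.0, 5.0, 1.0 / FS)
        y = np.full_like(t, 1.9)  # stays at 95% of settling, never decays
        with pytest.raises(MalformedSegmentError):
            fall_metrics(t, y, 0.0, 2.0)


class TestRelaxationTime:
    def test_arithmetic_and_label(self):
        rise = JetResponseMetrics(rise_time=0.9)
        fall = JetResponseMetrics(fall_time=0.4)
        t_rel, label = relaxation_time(rise, fall)
        assert t_rel == pytest.approx(0.5)
        assert label == "no-buildup"

    def test_equal_times_boundary(self):
        rise = JetResponseMetrics(rise_time=0.4)
        fall = JetResponseMetrics(fall_time=0.4)
        t_rel, label = relaxation_time(rise, fall)
        assert t_rel == 0.0 and label == "boundary"

    def test_first_order_envelopes_closed_form(self):
        """tau_rise 0.3, tau_fall 0.1 => t_rel = ln9 * 0.2."""
        t, yr = first_order_rise(0.3, amplitude=0.5, baseline=1.2)
        _, yf = first_order_fall(0.1, amplitude=0.5, baseline=1.2, span=9.0)
        rise = rise_metrics(t, yr, 1.2)
        fall = fall_metrics(t, yf, 1.2, rise.settling_value)
        t_rel, label = relaxation_time(rise, fall)
        assert t_rel == pytest.approx(LN9 * 0.2, abs=3.0 / FS)
        assert label == "no-buildup"

    def test_antisymmetry_under_swap(self):
        a = JetResponseMetrics(rise_time=0.7, fall_time=0.2)
        b = JetResponseMetrics(rise_time=0.2, fall_time=0.7)
        t_ab, _ = relaxation_time(a, a)
        t_ba, _ = relaxation_time(b, b)
        assert t_ab == pytest.approx(-t_ba)


class TestPulsedSummary:
    def test_identical_bursts_idempotent(self):
        m = JetResponseMetrics(baseline_value=1.2, settling_value=1.8,
                               rise_time=0.7, fall_time=0.3)
        s = pulsed_summary([m] * 5)
        assert s.rise_time == pytest.approx(0.7)
        assert s.relaxation_time == pytest.approx(0.4)

    def test_mean_across_bursts(self):
        bursts = [JetResponseMetrics(rise_time=r, fall_time=0.0)
                  for r in (0.1, 0.2, 0.3, 0.4, 0.5)]
        assert pulsed_summary(bursts).rise_time == pytest.approx(0.3)

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            pulsed_summary([])


class TestProperties:
    def test_error_at_least_halves_when_rate_doubles(self):
        """Discretization error of the rise time is O(1/fs^2) on average;
        a doubled sampling rate at least halves the grid-phase-averaged
        error at the study rate."""
        tau = 0.23

        def avg_err(fs):
            errs = []
            for off in np.linspace(0.0, 1.0 / fs, 20, endpoint=False):
                t = np.arange(0.0, 30 * tau, 1.0 / fs) + off
                y = 1.0 - np.exp(-(t - t[0]) / tau)
                errs.append(abs(rise_metrics(t, y, 0.0).rise_time - tau * LN9))
            return float(np.mean(errs))

        assert avg_err(200.0) <= 0.5 * avg_err(100.0) + 1e-7

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.05, 50.0), tau=st.floats(0.1, 0.5))
    def test_scale_invariance(self, scale, tau):
        """Scaling amplitude leaves timings unchanged, scales amplitudes."""
        t, y = first_order_rise(tau, amplitude=0.8, baseline=1.2, span=6.0)
        m1 = rise_metrics(t, y, 1.2)
        m2 = rise_metrics(t, y * scale, 1.2 * scale)
        assert m2.rise_time == pytest.approx(m1.rise_time, rel=1e-9)
        assert m2.settling_time == pytest.approx(m1.settling_time, rel=1e-9)
        assert m2.settling_value == pytest.approx(m1.settling_value * scale,
                                                  rel=1e-9)

    def test_combine_merges_fall_time(self):
        rise = JetResponseMetrics(rise_time=0.6, settling_value=1.8)
        fall = JetResponseMetrics(fall_time=0.2)
        merged = combine(rise, fall)
        assert merged.relaxation_time == pytest.approx(0.4)
        assert merged.settling_value == 1.8
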