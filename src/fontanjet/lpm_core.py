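"""Reduced-order four-compartment Windkessel model of Fontan circulation.

The mock flow loop this model emulates routes the output of a pulsatile
piston pump (the single functioning ventricle) through two systemic
resistance/compliance compartments (upper and lower body), merges the venous
return at an idealized total cavopulmonary connection (TCPC), and splits it
into the right and left pulmonary compartments, which drain into an atrial
reference reservoir.

Circuit topology
----------------
Each of the four named compartments is a compliance chamber plus one
resistance: the systemic resistances sit on the arterial inlet (they absorb
most of the arterial-to-venous pressure drop and set the upper/lower split),
the pulmonary resistances sit on the branch inlet from the TCPC junction
(they set the RPA/LPA split).  Small fixed "plumbing" elements close the
loop and are not tuned: a compliance at the pump outlet node, venous lines
from each systemic chamber to the junction, and drain lines from each
pulmonary chamber to the reservoir.  The TCPC junction itself is an ideal
zero-resistance node whose pressure is eliminated algebraically.  Any
external injection enters the RPA branch between the junction and the
distal flow sensor, so the measured RPA flow includes the injected flow.

State vector: ``(p_aortic, p_upper, p_lower, p_rpa, p_lpa)`` in mmHg.
Interface units: flow L/min, pressure mmHg, time s, resistance mmHg.min/L,
compliance mL/mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import (ConvergenceError, InsufficientWindowError,
                     InvalidParameterError, InvalidTargetError,
                     NumericStateError, TuningError)
from .injection_protocol import InjectionProtocol, injection_flow
from .waveform import WaveformRecord

_ML_PER_L_MIN_TO_ML_PER_S = 1000.0 / 60.0  # 1 L/min in mL/s

COMPARTMENT_NAMES = ("upper_systemic", "lower_systemic", "rpa", "lpa")
STATE_LAYOUT = ("p_aortic", "p_upper", "p_lower", "p_rpa", "p_lpa")


@dataclass(frozen=True)
class WindkesselCompartment:
    """A two-element (RC) vascular bed.

    resistance : mmHg.min/L, > 0
    compliance : mL/mmHg, > 0
    """

    name: str
    resistance: float
    compliance: float

    def __post_init__(self) -> None:
        if self.name not in COMPARTMENT_NAMES:
            raise InvalidParameterError(
                f"compartment name {self.name!r} not in {COMPARTMENT_NAMES}")
        for label, value in (("resistance", self.resistance),
                             ("compliance", self.compliance)):
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"{self.name}.{label} must be positive and finite, got {value}")


@dataclass(frozen=True)
class PumpSettings:
    """Pulsatile piston-pump source: half-sine ejection pulse.

    The pump ejects a half-sine flow pulse occupying
    ``ejection_fraction_of_cycle`` of each cardiac period and is quiescent
    for the remainder; the pulse area equals the stroke volume exactly, so
    cycle-averaged output is heart_rate x stroke_volume.
    """

    heart_rate: float = 80.0          # beats/min
    stroke_volume: float = 30.0       # mL
    ejection_fraction_of_cycle: float = 0.3

    def __post_init__(self) -> None:
        if not np.isfinite(self.heart_rate) or self.heart_rate <= 0:
            raise InvalidParameterError(f"heart_rate must be > 0, got {self.heart_rate}")
        if self.stroke_volume < 0:
            raise InvalidParameterError("stroke_volume must be >= 0")
        if not 0 < self.ejection_fraction_of_cycle < 1:
            raise InvalidParameterError("ejection_fraction_of_cycle must be in (0, 1)")

    @property
    def period(self) -> float:
        """Cardiac period, s."""
        return 60.0 / self.heart_rate

    @property
    def cardiac_output(self) -> float:
        """Cycle-averaged pump output, L/min."""
        return self.heart_rate * self.stroke_volume / 1000.0


@dataclass(frozen=True)
class PlumbingSettings:
    """Fixed rig plumbing closing the loop; not touched by tuning.

    aortic_compliance : mL/mmHg, pump-outlet chamber smoothing the ejection
        pulse (a piston pump into purely resistive lines would produce
        unphysiological pressure spikes).
    venous_resistance : mmHg.min/L, each systemic chamber -> TCPC line.
    drain_resistance  : mmHg.min/L, each pulmonary chamber -> reservoir line.
    """

    aortic_compliance: float = 0.8
    venous_resistance: float = 1.0
    drain_resistance: float = 2.25

    def __post_init__(self) -> None:
        for label in ("aortic_compliance", "venous_resistance", "drain_resistance"):
            v = getattr(self, label)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"plumbing.{label} must be > 0, got {v}")


@dataclass(frozen=True)
class LPMParameters:
    """Complete parameterization of the rig model."""

    compartments: tuple[WindkesselCompartment, ...]
    pump: PumpSettings = PumpSettings()
    venous_reference_pressure: float = 5.0   # mmHg, atrial reservoir
    systemic_split_target: float = 0.30      # upper-body share of CO
    pulmonary_split_target: float = 0.50     # RPA share of pulmonary return
    plumbing: PlumbingSettings = PlumbingSettings()

    def __post_init__(self) -> None:
        names = [c.name for c in self.compartments]
        if sorted(names) != sorted(COMPARTMENT_NAMES):
            raise InvalidParameterError(
                f"need exactly one compartment of each of {COMPARTMENT_NAMES}, got {names}")
        for target in (self.systemic_split_target, self.pulmonary_split_target):
            if not 0 < target < 1:
                raise InvalidTargetError(f"split target {target} outside (0, 1)")

    def compartment(self, name: str) -> WindkesselCompartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise InvalidParameterError(f"no compartment named {name!r}")

    def with_resistance(self, name: str, resistance: float) -> "LPMParameters":
        comps = tuple(replace(c, resistance=resistance) if c.name == name else c
                      for c in self.compartments)
        return replace(self, compartments=comps)


def default_parameters() -> LPMParameters:
    """Tuned default parameterization shipped with the package.

    Loaded from ``data/default_lpm.yaml`` (which records the tuning
    rationale); resistances reproduce the 30/70 systemic and 50/50
    pulmonary splits at CO = 2.4 L/min, with chamber pressures in the
    venous ~16-19 mmHg / pulmonary ~7-8 mmHg / aortic ~95-100 mmHg ranges.
    """
    from .config import load_parameters_yaml, _default_config_path
    return load_parameters_yaml(_default_config_path())


@dataclass(frozen=True)
class SimulationConfig:
    """Solver/output contract for :func:`simulate`.

    duration : s; must cover settle_cycles + 1 cardiac cycles.
    time_step : s; output sampling interval (sampling_rate = 1/time_step).
    settle_cycles : cycles discarded before periodicity is required.
    periodicity_tolerance : max relative change between consecutive
        cycle means of any flow channel at steady state.
    """

    duration: float = 20.0
    time_step: float = 0.01
    settle_cycles: int = 10
    periodicity_tolerance: float = 0.005

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise InvalidParameterError("time_step must be > 0")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")


# ---------------------------------------------------------------------------
# pump source
# ---------------------------------------------------------------------------

def pump_flow(t, pump: PumpSettings):
    """Pump outflow at time(s) ``t``, L/min.

    Half-sine pulse of duration ``ef*T`` each cycle with peak
    ``pi*SV/(2*T_ej)``; the per-cycle integral equals the stroke volume.
    """
    if pump.heart_rate <= 0:
        raise InvalidParameterError("heart_rate must be > 0")
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError("pump_flow requires t >= 0")
    period = pump.period
    t_ej = pump.ejection_fraction_of_cycle * period
    peak_ml_s = np.pi * pump.stroke_volume / (2.0 * t_ej)
    phase = np.mod(arr, period)
    y = np.where(phase < t_ej, peak_ml_s * np.sin(np.pi * phase / np.maximum(t_ej, 1e-300)), 0.0)
    y = y * 0.06  # mL/s -> L/min
    return float(y) if arr.ndim == 0 else y


# ---------------------------------------------------------------------------
# network equations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Coefficients:
    """Scalar circuit constants pre-extracted for the RHS hot loop."""

    r_up: float      # arterial inlet, upper systemic
    r_low: float
    r_rpa: float     # junction -> RPA chamber
    r_lpa: float
    c_a: float
    c_up: float
    c_low: float
    c_rpa: float
    c_lpa: float
    r_ven: float     # chamber -> junction, each systemic side
    r_drain: float   # chamber -> reservoir, each pulmonary side
    p_ref: float

    @classmethod
    def from_params(cls, params: LPMParameters) -> "_Coefficients":
        up = params.compartment("upper_systemic")
        low = params.compartment("lower_systemic")
        rpa = params.compartment("rpa")
        lpa = params.compartment("lpa")
        pl = params.plumbing
        return cls(up.resistance, low.resistance, rpa.resistance, lpa.resistance,
                   pl.aortic_compliance, up.compliance, low.compliance,
                   rpa.compliance, lpa.compliance,
                   pl.venous_resistance, pl.drain_resistance,
                   params.venous_reference_pressure)

    def junction_pressure(self, p_up: float, p_low: float,
                          p_rpa: float, p_lpa: float) -> float:
        g = (1.0 / self.r_ven, 1.0 / self.r_ven, 1.0 / self.r_rpa, 1.0 / self.r_lpa)
        num = p_up * g[0] + p_low * g[1] + p_rpa * g[2] + p_lpa * g[3]
        return num / sum(g)


def junction_pressure(state, params: LPMParameters) -> float:
    """Pressure of the ideal TCPC junction node for a given state."""
    c = _Coefficients.from_params(params)
    _, p_up, p_low, p_rpa, p_lpa = np.asarray(state, dtype=float)
    return c.junction_pressure(p_up, p_low, p_rpa, p_lpa)


def lpm_derivatives(state, t: float, params: LPMParameters,
                    external_inflows: Mapping[str, float] | None = None) -> np.ndarray:
    """Time derivatives of the compartment pressures, mmHg/s.

    ``state`` follows :data:`STATE_LAYOUT`.  ``external_inflows`` may carry
    ``"pump"`` (L/min into the aortic node; if absent the pump waveform at
    time ``t`` is used) and ``"injection"`` (L/min into the RPA branch node).
    Each compliance obeys C dP/dt = Q_in - Q_out with resistive branch flows
    Q = dP/R; the junction node is eliminated algebraically.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (5,):
        raise NumericStateError(f"state must have 5 entries ({STATE_LAYOUT}), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise NumericStateError(f"non-finite state: {y}")
    inflows = dict(external_inflows or {})
    q_pump = inflows.get("pump")
    if q_pump is None:
        q_pump = pump_flow(t, params.pump)
    q_inj = inflows.get("injection", 0.0)
    c = _Coefficients.from_params(params)
    return _rhs(c, y, q_pump, q_inj)


def _rhs(c: _Coefficients, y: np.ndarray, q_pump: float, q_inj: float) -> np.ndarray:
    p_a, p_up, p_low, p_rpa, p_lpa = y
    p_j = c.junction_pressure(p_up, p_low, p_rpa, p_lpa)
    q_art_up = (p_a - p_up) / c.r_up
    q_art_low = (p_a - p_low) / c.r_low
    q_ven_up = (p_up - p_j) / c.r_ven
    q_ven_low = (p_low - p_j) / c.r_ven
    q_rpa_in = (p_j - p_rpa) / c.r_rpa
    q_lpa_in = (p_j - p_lpa) / c.r_lpa
    q_rpa_out = (p_rpa - c.p_ref) / c.r_drain
    q_lpa_out = (p_lpa - c.p_ref) / c.r_drain
    k = _ML_PER_L_MIN_TO_ML_PER_S
    return np.array([
        k * (q_pump - q_art_up - q_art_low) / c.c_a,
        k * (q_art_up - q_ven_up) / c.c_up,
        k * (q_art_low - q_ven_low) / c.c_low,
        k * (q_rpa_in + q_inj - q_rpa_out) / c.c_rpa,
        k * (q_lpa_in - q_lpa_out) / c.c_lpa,
    ])


def _system_matrix(c: _Coefficients) -> np.ndarray:
    """Constant state matrix A of the LTI network, d(state)/dt = A.state + input."""
    k = _ML_PER_L_MIN_TO_ML_PER_S
    g = np.array([1.0 / c.r_ven, 1.0 / c.r_ven, 1.0 / c.r_rpa, 1.0 / c.r_lpa])
    w = g / g.sum()  # junction pressure weights over (p_up, p_low, p_rpa, p_lpa)
    a = np.zeros((5, 5))
    # aortic node
    a[0, 0] = -(1.0 / c.r_up + 1.0 / c.r_low)
    a[0, 1] = 1.0 / c.r_up
    a[0, 2] = 1.0 / c.r_low
    a[0] *= k / c.c_a
    # systemic chambers: inflow (p_a-p)/r_art, outflow (p - p_j)/r_ven
    for row, r_art, cap in ((1, c.r_up, c.c_up), (2, c.r_low, c.c_low)):
        a[row, 0] = 1.0 / r_art
        a[row, row] += -1.0 / r_art - 1.0 / c.r_ven
        a[row, 1:5] += w / c.r_ven
        a[row] *= k / cap
    # pulmonary chambers: inflow (p_j-p)/r_pa, outflow (p-p_ref)/r_drain
    for row, r_pa, cap in ((3, c.r_rpa, c.c_rpa), (4, c.r_lpa, c.c_lpa)):
        a[row, 1:5] = w / r_pa
        a[row, row] += -1.0 / r_pa - 1.0 / c.r_drain
        a[row] *= k / cap
    return a


def _periodic_init(params: LPMParameters) -> np.ndarray:
    """Initial state lying exactly on the no-injection periodic orbit.

    The network is LTI, so the no-injection cycle map is affine:
    x(T) = M x(0) + d with M = expm(A T).  Its fixed point is the periodic
    orbit's phase-0 state, which removes the slow (tens of seconds) settling
    transient that a plain DC initialization leaves in the venous flows.
    """
    from scipy.linalg import expm
    c = _Coefficients.from_params(params)
    period = params.pump.period
    m = expm(_system_matrix(c) * period)
    pump = params.pump
    t_ej = pump.ejection_fraction_of_cycle * period
    peak = np.pi * pump.stroke_volume / (2.0 * t_ej) * 0.06

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        phase = t % period
        q_pump = peak * np.sin(np.pi * phase / t_ej) if phase < t_ej else 0.0
        return _rhs(c, y, q_pump, 0.0)

    sol = solve_ivp(rhs, (0.0, period), np.zeros(5), method="LSODA",
                    max_step=period / 400.0, rtol=1e-9, atol=1e-11)
    d = sol.y[:, -1]
    try:
        return np.linalg.solve(np.eye(5) - m, d)
    except np.linalg.LinAlgError:  # pragma: no cover - stable networks only
        return _dc_state(params, pump.cardiac_output)


def _dc_state(params: LPMParameters, q_pump: float, q_inj: float = 0.0) -> np.ndarray:
    """Steady-state pressures for constant inflows (linear solve).

    Unknowns: (p_a, p_up, p_low, p_rpa, p_lpa, p_j).
    """
    c = _Coefficients.from_params(params)
    a = np.zeros((6, 6))
    b = np.zeros(6)

    def conduct(row, i, j, r):
        a[row, i] += 1.0 / r
        a[row, j] -= 1.0 / r

    # node a: (p_a-p_up)/r_up + (p_a-p_low)/r_low = q_pump
    conduct(0, 0, 1, c.r_up); conduct(0, 0, 2, c.r_low); b[0] = q_pump
    # node up: (p_a-p_up)/r_up = (p_up-p_j)/r_ven
    conduct(1, 1, 0, c.r_up); conduct(1, 1, 5, c.r_ven)
    # node low
    conduct(2, 2, 0, c.r_low); conduct(2, 2, 5, c.r_ven)
    # node rpa: (p_j-p_rpa)/r_rpa + q_inj = (p_rpa-p_ref)/r_drain
    a[3, 3] = 1.0 / c.r_rpa + 1.0 / c.r_drain
    a[3, 5] = -1.0 / c.r_rpa
    b[3] = q_inj + c.p_ref / c.r_drain
    # node lpa
    a[4, 4] = 1.0 / c.r_lpa + 1.0 / c.r_drain
    a[4, 5] = -1.0 / c.r_lpa
    b[4] = c.p_ref / c.r_drain
    # junction: inflow from systemics = outflow to pulmonary
    a[5, 1] = 1.0 / c.r_ven
    a[5, 2] = 1.0 / c.r_ven
    a[5, 3] = 1.0 / c.r_rpa
    a[5, 4] = 1.0 / c.r_lpa
    a[5, 5] = -(2.0 / c.r_ven + 1.0 / c.r_rpa + 1.0 / c.r_lpa)
    b[5] = 0.0
    sol = np.linalg.solve(a, b)
    return sol[:5]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(params: LPMParameters,
             protocol: InjectionProtocol | None = None,
             config: SimulationConfig = SimulationConfig()) -> WaveformRecord:
    """Integrate the rig model and return sampled flow/pressure channels.

    Channels: ``q_upper``/``q_lower`` (venous return at SVC/IVC, L/min),
    ``q_rpa``/``q_lpa`` (distal pulmonary branch flows; ``q_rpa`` includes
    the injected flow), and chamber pressures plus the aortic-analogue
    pressure (mmHg).  The state is initialized at the DC operating point so
    periodicity is reached within a few cycles; the pre-injection segment is
    checked for periodicity to ``config.periodicity_tolerance`` and a
    :class:`ConvergenceError` names the worst channel on failure.
    """
    period = params.pump.period
    if config.duration < (config.settle_cycles + 1) * period:
        raise InvalidParameterError(
            f"duration {config.duration}s does not cover settle_cycles+1 "
            f"({config.settle_cycles + 1}) cardiac cycles of {period}s")

    c = _Coefficients.from_params(params)
    pump = params.pump
    t_ej = pump.ejection_fraction_of_cycle * period
    peak = np.pi * pump.stroke_volume / (2.0 * t_ej) * 0.06  # L/min

    if protocol is not None:
        inj: Callable[[float], float] = lambda t: float(injection_flow(t, protocol))
    else:
        inj = lambda t: 0.0

    def pump_scalar(t: float) -> float:
        phase = t % period
        return peak * np.sin(np.pi * phase / t_ej) if phase < t_ej else 0.0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return _rhs(c, y, pump_scalar(t), inj(t))

    y0 = _periodic_init(params)
    t_eval = np.arange(0.0, config.duration + 0.5 * config.time_step, config.time_step)
    t_eval = t_eval[t_eval <= config.duration + 1e-12]
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), y0, method="LSODA",
                    t_eval=t_eval, max_step=min(period / 200.0, config.time_step),
                    rtol=1e-7, atol=1e-9)
    if not sol.success:
        raise ConvergenceError(f"integrator failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        raise NumericStateError("non-finite solver output")

    p_a, p_up, p_low, p_rpa, p_lpa = y
    g = (1.0 / c.r_ven, 1.0 / c.r_ven, 1.0 / c.r_rpa, 1.0 / c.r_lpa)
    p_j = (p_up * g[0] + p_low * g[1] + p_rpa * g[2] + p_lpa * g[3]) / sum(g)
    q_inj_t = (injection_flow(t_eval, protocol) if protocol is not None
               else np.zeros_like(t_eval))
    channels = {
        "q_upper": (p_up - p_j) / c.r_ven,
        "q_lower": (p_low - p_j) / c.r_ven,
        "q_rpa": (p_j - p_rpa) / c.r_rpa + q_inj_t,
        "q_lpa": (p_j - p_lpa) / c.r_lpa,
        "p_upper": p_up,
        "p_lower": p_low,
        "p_rpa": p_rpa,
        "p_lpa": p_lpa,
        "p_aortic": p_a,
    }
    metadata = {
        "provenance": "simulated",
        "heart_rate": pump.heart_rate,
        "stroke_volume": pump.stroke_volume,
        "settle_cycles": config.settle_cycles,
    }
    if protocol is not None:
        metadata.update(case_id=protocol.case_id, mode=protocol.mode,
                        injection_rate_l_min=protocol.rate_l_min,
                        injection_start=protocol.start_time)
    record = WaveformRecord(t_eval, channels, 1.0 / config.time_step, metadata)
    _check_periodicity(record, params, protocol, config)
    return record


def _check_periodicity(record: WaveformRecord, params: LPMParameters,
                       protocol: InjectionProtocol | None,
                       config: SimulationConfig) -> None:
    """Require consecutive settled pre-injection cycle means to agree."""
    period = params.pump.period
    limit = protocol.start_time if protocol is not None else record.time[-1]
    n_cycles = int(np.floor((min(limit, record.time[-1]) + 1e-9) / period))
    first = config.settle_cycles
    if n_cycles < first + 2:
        raise ConvergenceError(
            f"pre-injection span holds only {n_cycles} cycles; periodicity "
            f"cannot be verified after {first} settle cycles")
    worst = ("", 0.0)
    for name in ("q_upper", "q_lower", "q_rpa", "q_lpa"):
        x = record.channel(name)
        means = []
        for k in range(first, n_cycles):
            mask = (record.time >= k * period) & (record.time < (k + 1) * period)
            means.append(float(np.mean(x[mask])))
        rel = max(abs(means[i + 1] - means[i]) / max(abs(means[i]), 1e-9)
                  for i in range(len(means) - 1))
        if rel > worst[1]:
            worst = (name, rel)
    if worst[1] > config.periodicity_tolerance:
        raise ConvergenceError(
            f"periodicity not reached within {config.settle_cycles} settle cycles: "
            f"channel {worst[0]!r} cycle-mean change {worst[1]:.3g} "
            f"> {config.periodicity_tolerance}")


# ---------------------------------------------------------------------------
# averaging & tuning
# ---------------------------------------------------------------------------

def cycle_average(record: WaveformRecord, channel: str,
                  window: tuple[float, float]) -> float:
    """Mean of a channel over an integer number of cardiac cycles.

    The window is truncated to the largest whole number of cycles that fits
    (partial trailing cycles are dropped); a window shorter than one cycle
    raises :class:`InsufficientWindowError`.
    """
    hr = float(record.metadata.get("heart_rate", 80.0))
    period = 60.0 / hr
    t0, t1 = window
    if t0 < record.time[0] - 1e-9 or t1 > record.time[-1] + 1e-9:
        raise InsufficientWindowError(
            f"window {window} outside record extent "
            f"[{record.time[0]}, {record.time[-1]}]")
    n = int(np.floor((t1 - t0) / period + 1e-9))
    if n < 1:
        raise InsufficientWindowError(
            f"window of {t1 - t0:.3g}s is shorter than one cardiac cycle ({period:.3g}s)")
    mask = (record.time >= t0 - 1e-12) & (record.time < t0 + n * period - 1e-12)
    return float(np.mean(record.channel(channel)[mask]))


def measured_splits(record: WaveformRecord,
                    window: tuple[float, float]) -> tuple[float, float]:
    """(upper-systemic share of CO, RPA share of pulmonary return)."""
    q_up = cycle_average(record, "q_upper", window)
    q_low = cycle_average(record, "q_lower", window)
    q_rpa = cycle_average(record, "q_rpa", window)
    q_lpa = cycle_average(record, "q_lpa", window)
    return q_up / (q_up + q_low), q_rpa / (q_rpa + q_lpa)


def _tuning_config(params: LPMParameters) -> SimulationConfig:
    period = params.pump.period
    settle = 8
    return SimulationConfig(duration=(settle + 4) * period, time_step=0.005,
                            settle_cycles=settle, periodicity_tolerance=0.01)


def tune_resistances(params: LPMParameters,
                     config: SimulationConfig | None = None,
                     tol: float = 1e-3) -> LPMParameters:
    """Adjust resistances until the simulated flow splits meet the targets.

    Two sequential 1-D root searches (they are independent in this
    topology): the upper-systemic resistance is scaled until the upper-body
    share of CO equals ``systemic_split_target``, then the RPA resistance is
    scaled until the RPA share of pulmonary return equals
    ``pulmonary_split_target``, each to ``tol`` on the split fraction.
    Deterministic; returns the input unchanged when already within
    tolerance, so re-tuning tuned parameters is exactly idempotent.
    """
    for target in (params.systemic_split_target, params.pulmonary_split_target):
        if not 0 < target < 1:
            raise InvalidTargetError(f"split target {target} outside (0, 1)")
    cfg = config or _tuning_config(params)
    window = (cfg.settle_cycles * params.pump.period, cfg.duration)

    def splits_for(p: LPMParameters) -> tuple[float, float]:
        return measured_splits(simulate(p, None, cfg), window)

    current = params
    sys_split, pul_split = splits_for(current)

    if abs(sys_split - current.systemic_split_target) > tol:
        base_r = current.compartment("upper_systemic").resistance

        def sys_resid(log_scale: float) -> float:
            p = current.with_resistance("upper_systemic", base_r * np.exp(log_scale))
            return splits_for(p)[0] - current.systemic_split_target

        current = current.with_resistance(
            "upper_systemic", base_r * np.exp(_solve(sys_resid, tol)))

    pul_split = splits_for(current)[1]
    if abs(pul_split - current.pulmonary_split_target) > tol:
        base_r = current.compartment("rpa").resistance

        def pul_resid(log_scale: float) -> float:
            p = current.with_resistance("rpa", base_r * np.exp(log_scale))
            return splits_for(p)[1] - current.pulmonary_split_target

        current = current.with_resistance(
            "rpa", base_r * np.exp(_solve(pul_resid, tol)))

    sys_split, pul_split = splits_for(current)
    resid = (abs(sys_split - current.systemic_split_target),
             abs(pul_split - current.pulmonary_split_target))
    if max(resid) > 5 * tol:
        raise TuningError(f"tuning residuals {resid} exceed tolerance {tol}")
    return current


def _solve(resid: Callable[[float], float], tol: float) -> float:
    """Root of a monotone residual in log-scale, with bracket expansion."""
    lo, hi = -0.3, 0.3
    f_lo, f_hi = resid(lo), resid(hi)
    for _ in range(12):
        if f_lo * f_hi <= 0:
            break
        lo, hi = lo * 2.0, hi * 2.0
        f_lo, f_hi = resid(lo), resid(hi)
    else:
        raise TuningError(f"could not bracket the split target; residuals "
                          f"({f_lo:.4g}, {f_hi:.4g}) at log-scales ({lo}, {hi})")
    return float(brentq(resid, lo, hi, xtol=1e-4, rtol=1e-6))
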