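"""Synthetic mock-flow-loop sensor records with known ground truth.

This module stands in for the benchtop rig: it runs the lumped-parameter
circulation model, superimposes a programmable jet-entrainment response on
the RPA flow channel, and adds seeded sensor noise (white Gaussian plus a
mains tone).  Because the entrainment magnitude and envelope time constants
are programmed, every downstream stage (filtering, segmentation, step
metrics, entrainment quantification) can be validated by parameter recovery.

Composition contract for the RPA channel::

    q_rpa(t) = [no-injection LPM RPA flow](t) + [lagged injection flow](t)
               + E(t) + noise

where E(t) is a first-order envelope locked to the injection command
(plateau ``magnitude``, time constants ``tau_rise`` on activation and
``tau_fall`` on shutoff).  All other channels come from a with-injection LPM
run, so the transient systemic-flow dips during injection arise from the
circulation model's own volume bookkeeping.

The mains tone is synthesized in continuous time and then sampled: below
the Nyquist rate it shows up aliased, exactly as a real DAQ records it
(60 Hz appears at 40 Hz when sampling at 100 Hz); either way it lies far
above the low-pass cutoff of the filtering stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AliasingError, InvalidParameterError
from .injection_protocol import InjectionProtocol, injection_flow
from .jet_characterization import fall_metrics, relaxation_time, rise_metrics
from .lpm_core import LPMParameters, SimulationConfig, cycle_average, simulate
from .waveform import WaveformRecord, read_waveform_csv, write_waveform_csv

__all__ = [
    "SensorModel", "EntrainmentEmulation", "emulate_mfl", "compose_noiseless",
    "add_sensor_noise", "entrainment_envelope", "write_waveform_csv",
    "read_waveform_csv", "WaveformRecord",
]


@dataclass(frozen=True)
class SensorModel:
    """Sampling and noise model of the rig's DAQ chain.

    Noise is additive per channel: white Gaussian with the stated SD plus a
    mains tone of random phase.  100 Hz sampling resolves the sub-second
    rise/fall times of interest with >= 10 samples.
    """

    sampling_rate: float = 100.0       # Hz
    flow_noise_sd: float = 0.05        # L/min
    pressure_noise_sd: float = 0.5     # mmHg
    mains_frequency: float = 60.0      # Hz
    mains_amplitude_flow: float = 0.1  # L/min
    mains_amplitude_pressure: float = 1.0  # mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        for f in ("flow_noise_sd", "pressure_noise_sd",
                  "mains_amplitude_flow", "mains_amplitude_pressure"):
            if getattr(self, f) < 0:
                raise InvalidParameterError(f"{f} must be >= 0")

    def noise_sd(self, channel: str) -> float:
        return self.flow_noise_sd if channel.startswith("q_") else self.pressure_noise_sd

    def mains_amplitude(self, channel: str) -> float:
        return (self.mains_amplitude_flow if channel.startswith("q_")
                else self.mains_amplitude_pressure)


@dataclass(frozen=True)
class EntrainmentEmulation:
    """Programmed ground-truth entrainment response.

    magnitude : L/min; plateau entrainment E0 (negative = blockage).
    tau_rise / tau_fall : s; first-order envelope time constants on
        command activation / shutoff.
    """

    magnitude: float = 0.0
    tau_rise: float = 0.35
    tau_fall: float = 0.15

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_fall <= 0:
            raise InvalidParameterError("tau_rise and tau_fall must be > 0")


def entrainment_envelope(t: np.ndarray, windows: list[tuple[float, float]],
                         emulation: EntrainmentEmulation) -> np.ndarray:
    """First-order envelope E(t) driven by the command on/off schedule.

    While the command is on, E relaxes toward ``magnitude`` with
    ``tau_rise``; while off, toward 0 with ``tau_fall``.  Evaluated
    analytically segment by segment, so it is exact on any grid.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    events: list[tuple[float, float, float]] = []  # (start, target, tau)
    for on, off in windows:
        events.append((on, emulation.magnitude, emulation.tau_rise))
        events.append((off, 0.0, emulation.tau_fall))
    events.sort()
    level = 0.0
    for i, (start, target, tau) in enumerate(events):
        end = events[i + 1][0] if i + 1 < len(events) else np.inf
        mask = (t >= start) & (t < end)
        out[mask] = target + (level - target) * np.exp(-(t[mask] - start) / tau)
        level = target + (level - target) * math.exp(-(end - start) / tau) \
            if np.isfinite(end) else target
    return out


def _auto_config(protocol: InjectionProtocol | None, sensor: SensorModel,
                 post_margin: float = 10.0) -> SimulationConfig:
    end = protocol.end_time + post_margin if protocol is not None else 20.0
    return SimulationConfig(duration=float(np.ceil(end)),
                            time_step=1.0 / sensor.sampling_rate)


def compose_noiseless(params: LPMParameters,
                      protocol: InjectionProtocol | None,
                      entrainment: EntrainmentEmulation = EntrainmentEmulation(),
                      config: SimulationConfig | None = None,
                      compute_ground_truth: bool = True,
                      sampling_rate: float = 100.0) -> WaveformRecord:
    """Deterministic (noise-free) emulated record with ground-truth metadata."""
    if sampling_rate < 2.0 * params.pump.heart_rate / 60.0:
        raise AliasingError(
            f"sampling rate {sampling_rate} Hz below twice the heart frequency "
            f"({params.pump.heart_rate / 60.0:.2f} Hz)")
    cfg = config or _auto_config(protocol, SensorModel(sampling_rate=sampling_rate))
    base = simulate(params, None, cfg)
    if protocol is None:
        rec = base.copy_with(gt_e0=entrainment.magnitude)
        return rec
    injected = simulate(params, protocol, cfg)
    t = base.time
    env = entrainment_envelope(t, protocol.command_windows(), entrainment)
    q_rpa = base.channel("q_rpa") + np.asarray(injection_flow(t, protocol)) + env
    channels = dict(injected.channels)
    channels["q_rpa"] = q_rpa
    meta = {**injected.metadata,
            "gt_e0": entrainment.magnitude,
            "gt_tau_rise": entrainment.tau_rise,
            "gt_tau_fall": entrainment.tau_fall}
    rec = WaveformRecord(t.copy(), channels, base.sampling_rate, meta)
    if compute_ground_truth:
        rec.metadata.update(_ground_truth_metrics(rec, protocol))
    return rec


def _ground_truth_metrics(record: WaveformRecord,
                          protocol: InjectionProtocol) -> dict[str, float]:
    """Reference rise/fall/relaxation of the noiseless composite RPA flow."""
    period = 60.0 / float(record.metadata.get("heart_rate", 80.0))
    n_base = int((protocol.start_time - record.time[0]) / period)
    baseline = cycle_average(record, "q_rpa",
                             (protocol.start_time - min(n_base, 8) * period,
                              protocol.start_time))
    t = record.time
    q = record.channel("q_rpa")
    rises, falls = [], []
    windows = protocol.command_windows()
    for i, (on, off) in enumerate(windows):
        next_on = windows[i + 1][0] if i + 1 < len(windows) else t[-1]
        rise_mask = (t >= on) & (t < off)
        fall_mask = (t >= off) & (t < min(next_on, off + 8.0))
        rise = rise_metrics(t[rise_mask], q[rise_mask], baseline)
        fall = fall_metrics(t[fall_mask], q[fall_mask], baseline, rise.settling_value)
        rises.append(rise.rise_time)
        falls.append(fall.fall_time)
    t_rise = float(np.mean(rises))
    t_fall = float(np.mean(falls))
    return {"gt_baseline_rpa": baseline, "gt_t_rise": t_rise,
            "gt_t_fall": t_fall, "gt_t_rel": t_rise - t_fall}


def add_sensor_noise(record: WaveformRecord, sensor: SensorModel) -> WaveformRecord:
    """Add seeded Gaussian + mains noise to every channel.

    Identical (record, sensor) inputs yield bitwise-identical output;
    different seeds change only the noise component.
    """
    rng = np.random.default_rng(sensor.seed)
    t = record.time
    channels: dict[str, np.ndarray] = {}
    for name in sorted(record.channels):
        x = record.channels[name]
        phase = rng.uniform(0.0, 2.0 * np.pi)
        noise = rng.normal(0.0, 1.0, x.size) * sensor.noise_sd(name)
        mains = sensor.mains_amplitude(name) * np.sin(
            2.0 * np.pi * sensor.mains_frequency * t + phase)
        channels[name] = x + noise + mains
    return record.copy_with(channels=channels, seed=sensor.seed,
                            provenance="simulated")


def emulate_mfl(params: LPMParameters,
                protocol: InjectionProtocol | None,
                sensor: SensorModel = SensorModel(),
                entrainment: EntrainmentEmulation = EntrainmentEmulation(),
                config: SimulationConfig | None = None) -> WaveformRecord:
    """Full emulated sensor record: LPM + injection + entrainment + noise."""
    clean = compose_noiseless(params, protocol, entrainment,
                              config=config or _auto_config(protocol, sensor),
                              sampling_rate=sensor.sampling_rate)
    clean.metadata["sensor_seed"] = sensor.seed
    return add_sensor_noise(clean, sensor)
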