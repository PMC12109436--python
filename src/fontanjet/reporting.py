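"""End-to-end protocol sweeps and result-table emission.

``run_sweep`` drives the whole pipeline for every requested protocol case
and trial: emulate the rig record, filter it, segment the stages and
bursts, characterize the step response, and quantify entrainment.  It
writes a long-form per-trial CSV, trial-averaged entrainment and relaxation
matrices for each injection mode, and a JSON manifest with every seed and a
config hash, so re-running with the same configuration reproduces
byte-identical outputs.

Per-trial seeds are derived deterministically from
(base_seed, case_id, trial) via BLAKE2, so any single trial can be
re-generated in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import printed_tables
from .entrainment import (EntrainmentMatrix, EntrainmentResult,
                          entrainment_matrix, measure_entrainment)
from .errors import FontanJetError
from .injection_protocol import InjectionProtocol, protocol_table
from .jet_characterization import (JetResponseMetrics, combine, fall_metrics,
                                   pulsed_summary, relaxation_time,
                                   rise_metrics)
from .lpm_core import (LPMParameters, SimulationConfig, cycle_average,
                       default_parameters, tune_resistances)
from .segmentation import segment_bursts, segment_stages
from .signal_processing import FilterConfig, filter_record
from .synthetic_mfl import (EntrainmentEmulation, SensorModel,
                            add_sensor_noise, compose_noiseless)
from .waveform import WaveformRecord

log = logging.getLogger("fontanjet.sweep")


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a protocol sweep (cases x trials)."""

    cases: tuple[int, ...] | str = "all"
    trials_per_case: int = 3
    base_seed: int = 0
    output_dir: str | None = None
    params: LPMParameters | None = None   # tuned LPM; defaults if None
    sensor: SensorModel = SensorModel()
    filter: FilterConfig = FilterConfig()
    tau_rise: float = 0.35                # entrainment envelope, s
    tau_fall: float = 0.15
    retune: bool = False                  # re-run tune_resistances first

    def __post_init__(self) -> None:
        if self.trials_per_case < 1:
            raise FontanJetError("trials_per_case must be >= 1")

    def case_ids(self) -> list[int]:
        if self.cases == "all":
            return list(range(1, 21))
        return list(self.cases)  # type: ignore[arg-type]


def trial_seed(base_seed: int, case_id: int, trial: int) -> int:
    """Deterministic per-trial seed below 2^31."""
    digest = hashlib.blake2b(f"{base_seed}:{case_id}:{trial}".encode(),
                             digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


def default_emulation_for_case(protocol: InjectionProtocol,
                               tau_rise: float = 0.35,
                               tau_fall: float = 0.15) -> EntrainmentEmulation:
    """Ground-truth emulation settings for a standard protocol case.

    The programmed entrainment magnitude is the published measured value
    for that (mode, rate, volume) cell, so a full sweep of the emulator
    reproduces the published entrainment landscape.
    """
    e0 = printed_tables.reference_entrainment(
        protocol.mode, protocol.rate_l_min, protocol.total_volume_l,
        protocol.burst_volume_ml / 1000.0)
    return EntrainmentEmulation(magnitude=e0, tau_rise=tau_rise, tau_fall=tau_fall)


@dataclass
class SweepReport:
    """In-memory result bundle of one sweep."""

    trials: pd.DataFrame
    entrainment_matrices: dict[str, EntrainmentMatrix]
    relaxation_matrices: dict[str, pd.DataFrame]
    manifest: dict
    failures: list[dict] = field(default_factory=list)


def analyze_record(record: WaveformRecord, protocol: InjectionProtocol,
                   filter_config: FilterConfig = FilterConfig(),
                   pulmonary_split: float = 0.5,
                   ) -> tuple[JetResponseMetrics, EntrainmentResult]:
    """Filter -> segment -> characterize -> entrainment for one record."""
    filtered = filter_record(record, filter_config)
    bounds = segment_stages(filtered, protocol, method="command_aligned")
    bounds = segment_bursts(bounds, filtered, protocol.burst_count,
                            protocol, method="command_aligned")
    baseline = cycle_average(filtered, "q_rpa", bounds.pre)
    t = filtered.time
    q = filtered.channel("q_rpa")
    per_burst: list[JetResponseMetrics] = []
    for (a_on, a_off), (s_on, s_off) in zip(bounds.injection_periods,
                                            bounds.shutoff_periods):
        rise_mask = (t >= a_on) & (t < a_off)
        fall_mask = (t >= s_on) & (t < s_off)
        rise = rise_metrics(t[rise_mask], q[rise_mask], baseline)
        fall = fall_metrics(t[fall_mask], q[fall_mask], baseline, rise.settling_value)
        per_burst.append(combine(rise, fall))
    metrics = pulsed_summary(per_burst)
    result = measure_entrainment(filtered, bounds, protocol,
                                 pulmonary_split=pulmonary_split,
                                 rise_metrics=metrics)
    return metrics, result


def run_sweep(config: SweepConfig) -> SweepReport:
    """Execute the configured sweep; see the module docstring."""
    params = config.params or default_parameters()
    if config.retune:
        params = tune_resistances(params)
    rows: list[dict] = []
    failures: list[dict] = []
    results_by_case: dict[int, list[EntrainmentResult]] = {}
    trel_by_case: dict[int, list[float]] = {}
    protocols = {p.case_id: p for p in protocol_table()}

    for case_id in config.case_ids():
        protocol = protocols[case_id]
        emu = default_emulation_for_case(protocol, config.tau_rise, config.tau_fall)
        try:
            clean = compose_noiseless(params, protocol, emu,
                                      sampling_rate=config.sensor.sampling_rate)
        except FontanJetError as exc:
            log.error("case %d: emulation failed: %s", case_id, exc)
            failures.append({"case": case_id, "trial": None, "error": str(exc)})
            continue
        for trial in range(config.trials_per_case):
            seed = trial_seed(config.base_seed, case_id, trial)
            try:
                sensor = SensorModel(
                    sampling_rate=config.sensor.sampling_rate,
                    flow_noise_sd=config.sensor.flow_noise_sd,
                    pressure_noise_sd=config.sensor.pressure_noise_sd,
                    mains_frequency=config.sensor.mains_frequency,
                    mains_amplitude_flow=config.sensor.mains_amplitude_flow,
                    mains_amplitude_pressure=config.sensor.mains_amplitude_pressure,
                    seed=seed)
                record = add_sensor_noise(clean, sensor)
                metrics, result = analyze_record(record, protocol, config.filter)
            except FontanJetError as exc:
                log.error("case %d trial %d: %s", case_id, trial, exc)
                failures.append({"case": case_id, "trial": trial, "error": str(exc)})
                continue
            t_rel, buildup = relaxation_time(metrics, metrics)
            rows.append({
                "case": case_id, "trial": trial, "seed": seed,
                "mode": protocol.mode,
                "rate_l_min": protocol.rate_l_min,
                "total_volume_l": protocol.total_volume_l,
                "burst_volume_l": protocol.burst_volume_ml / 1000.0,
                "q_meas_rpa": result.q_meas_rpa,
                "q_baseline_rpa": result.q_baseline_rpa,
                "q_ent": result.q_ent,
                "normalized": result.normalized,
                "label": result.label,
                "gt_e0": emu.magnitude,
                "rise_time": metrics.rise_time,
                "fall_time": metrics.fall_time,
                "relaxation_time": t_rel,
                "buildup_label": buildup,
                "settling_time": metrics.settling_time,
                "overshoot_pct": metrics.overshoot_pct,
                "undershoot_pct": metrics.undershoot_pct,
            })
            results_by_case.setdefault(case_id, []).append(result)
            trel_by_case.setdefault(case_id, []).append(t_rel)

    trials = pd.DataFrame(rows)
    ent_matrices: dict[str, EntrainmentMatrix] = {}
    rel_matrices: dict[str, pd.DataFrame] = {}
    for mode, volume_key in (("continuous", "total"), ("pulsed", "burst")):
        means: list[EntrainmentResult] = []
        rel_cells: dict[tuple[float, float], float] = {}
        for case_id, results in sorted(results_by_case.items()):
            proto = protocols[case_id]
            if proto.mode != mode:
                continue
            q_ent = float(pd.Series([r.q_ent for r in results]).mean())
            means.append(EntrainmentResult(
                q_meas_rpa=float(pd.Series([r.q_meas_rpa for r in results]).mean()),
                q_baseline_rpa=float(pd.Series(
                    [r.q_baseline_rpa for r in results]).mean()),
                q_inj=proto.rate_l_min, q_ent=q_ent,
                label="entrainment" if q_ent > 0 else "blockage",
                protocol=proto))
            vol = (proto.total_volume_l if volume_key == "total"
                   else proto.burst_volume_ml / 1000.0)
            rel_cells[(round(vol, 6), round(proto.rate_l_min, 6))] = float(
                pd.Series(trel_by_case[case_id]).mean())
        if means:
            try:
                ent_matrices[mode] = entrainment_matrix(means, mode, volume_key)
            except FontanJetError as exc:
                log.warning("incomplete %s sweep: %s", mode, exc)
                failures.append({"case": None, "trial": None,
                                 "error": f"incomplete {mode} matrix: {exc}"})
            vols = sorted({k[0] for k in rel_cells})
            rates = sorted({k[1] for k in rel_cells})
            rel_matrices[mode] = pd.DataFrame(
                [[rel_cells.get((v, r)) for r in rates] for v in vols],
                index=vols, columns=rates)

    manifest = {
        "base_seed": config.base_seed,
        "cases": config.case_ids(),
        "trials_per_case": config.trials_per_case,
        "seeds": {f"{r['case']}:{r['trial']}": r["seed"] for r in rows},
        "sensor": {"sampling_rate": config.sensor.sampling_rate,
                   "flow_noise_sd": config.sensor.flow_noise_sd,
                   "pressure_noise_sd": config.sensor.pressure_noise_sd,
                   "mains_frequency": config.sensor.mains_frequency,
                   "mains_amplitude_flow": config.sensor.mains_amplitude_flow},
        "filter": {"butterworth_order": config.filter.butterworth_order,
                   "butterworth_cutoff": config.filter.butterworth_cutoff,
                   "sg_window": config.filter.sg_window,
                   "sg_polyorder": config.filter.sg_polyorder},
        "envelope": {"tau_rise": config.tau_rise, "tau_fall": config.tau_fall},
        "n_failures": len(failures),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]

    report = SweepReport(trials, ent_matrices, rel_matrices, manifest, failures)
    if config.output_dir is not None:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: SweepReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.trials.to_csv(outdir / "trials.csv", index=False, float_format="%.10g")
    for mode, matrix in report.entrainment_matrices.items():
        matrix.values.to_csv(outdir / f"entrainment_{mode}.csv",
                             index_label="V_inj_L", float_format="%.10g")
    for mode, df in report.relaxation_matrices.items():
        df.to_csv(outdir / f"relaxation_{mode}.csv",
                  index_label="V_inj_L", float_format="%.10g")
    (outdir / "manifest.json").write_text(
        json.dumps({**report.manifest, "failures": report.failures},
                   indent=2, sort_keys=True))


def load_printed_tables() -> dict[str, object]:
    """The published result matrices as packaged fixtures.

    Returns entrainment matrices (:class:`EntrainmentMatrix`) and relaxation
    time tables (DataFrame) keyed by
    ``entrainment_continuous | entrainment_pulsed |
    relaxation_continuous | relaxation_pulsed``.
    """
    return {
        "entrainment_continuous": printed_tables.continuous_entrainment_matrix(),
        "entrainment_pulsed": printed_tables.pulsed_entrainment_matrix(),
        "relaxation_continuous": printed_tables.CONTINUOUS_RELAXATION.copy(),
        "relaxation_pulsed": printed_tables.PULSED_RELAXATION.copy(),
    }
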