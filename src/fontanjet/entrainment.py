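"""Jet entrainment quantification and sweep-level summaries.

The entrainment flow rate compares the measured RPA flow distal to the
injection site against what superposition alone would predict::

    Q_ent = Q_meas,RPA - (Q_baseline,RPA + Q_inj)

where ``Q_baseline,RPA`` is the expected RPA flow from the systemic flow
Q_s and the pulmonary flow split, and ``Q_inj`` is the commanded injection
rate.  A positive Q_ent means the jet entrains additional co-flow; a
negative Q_ent means the injection impedes (blocks) the native flow.  The
formula is deliberately parenthesized as above: only this reading makes the
sign semantics coherent.

Sweep results over the (injection volume x injection rate) grid are
assembled into matrices mirroring the experiment's reporting layout, from
which the per-rate normalized means ``mean(Q_ent)/Q_inj`` and the
entrainment cutoff rate (largest injection rate whose whole column is
positive) are derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (AlignmentError, IncompleteSweepError,
                     InsufficientWindowError, InvalidParameterError,
                     UndefinedNormalizationError)
from .injection_protocol import InjectionProtocol
from .jet_characterization import JetResponseMetrics
from .lpm_core import cycle_average
from .segmentation import StageBoundaries
from .waveform import WaveformRecord

#: |Q_ent| below this dead-band (L/min) is labelled neutral
NEUTRAL_DEADBAND = 1e-6


@dataclass(frozen=True)
class EntrainmentResult:
    """Entrainment quantification of one experimental run (or trial)."""

    q_meas_rpa: float          # active-window cycle-averaged RPA flow, L/min
    q_baseline_rpa: float      # expected RPA flow = Q_s x split, L/min
    q_inj: float               # commanded injection rate, L/min
    q_ent: float               # entrainment rate, L/min
    label: str                 # entrainment | blockage | neutral
    protocol: InjectionProtocol | None = None

    @property
    def normalized(self) -> float:
        """Q_ent / Q_inj; undefined for zero injection rate."""
        if self.q_inj <= 0:
            raise UndefinedNormalizationError(
                "normalized entrainment undefined for q_inj = 0")
        return self.q_ent / self.q_inj


def baseline_rpa(q_systemic: float, pulmonary_split: float) -> float:
    """Expected RPA flow from the systemic flow and the pulmonary split."""
    if not 0 <= pulmonary_split < 1:
        raise InvalidParameterError(f"pulmonary split {pulmonary_split} outside [0, 1)")
    return q_systemic * pulmonary_split


def entrainment_rate(q_meas_rpa: float, q_baseline_rpa: float, q_inj: float,
                     protocol: InjectionProtocol | None = None,
                     deadband: float = NEUTRAL_DEADBAND) -> EntrainmentResult:
    """Entrainment flow rate Q_ent = Q_meas - (Q_baseline + Q_inj)."""
    for name, v in (("q_meas_rpa", q_meas_rpa), ("q_baseline_rpa", q_baseline_rpa),
                    ("q_inj", q_inj)):
        if not np.isfinite(v):
            raise InvalidParameterError(f"{name} must be finite, got {v}")
    if q_inj < 0:
        raise InvalidParameterError(f"q_inj must be >= 0, got {q_inj}")
    q_ent = q_meas_rpa - (q_baseline_rpa + q_inj)
    label = ("neutral" if abs(q_ent) <= deadband
             else "entrainment" if q_ent > 0 else "blockage")
    return EntrainmentResult(q_meas_rpa, q_baseline_rpa, q_inj, q_ent, label, protocol)


def normalized_entrainment_series(q_with: np.ndarray, q_without: np.ndarray,
                                  q_ijs_mean: float,
                                  time_with: np.ndarray | None = None,
                                  time_without: np.ndarray | None = None) -> np.ndarray:
    """Pointwise normalized entrainment, in percent.

    ``100 * (q_with - q_without) / q_ijs_mean`` — the relative change in
    flow with vs without the injection jet shunt, normalized by the
    cycle-averaged jet flow rate.
    """
    q_with = np.asarray(q_with, dtype=float)
    q_without = np.asarray(q_without, dtype=float)
    if q_with.shape != q_without.shape:
        raise AlignmentError(
            f"series lengths differ: {q_with.shape} vs {q_without.shape}")
    if time_with is not None and time_without is not None and \
            not np.allclose(time_with, time_without, rtol=0, atol=1e-9):
        raise AlignmentError("series do not share a time base")
    if q_ijs_mean <= 0:
        raise UndefinedNormalizationError("q_ijs_mean must be > 0")
    return 100.0 * (q_with - q_without) / q_ijs_mean


# ---------------------------------------------------------------------------
# record-level measurement
# ---------------------------------------------------------------------------

def measure_entrainment(record: WaveformRecord, boundaries: StageBoundaries,
                        protocol: InjectionProtocol,
                        pulmonary_split: float = 0.5,
                        rise_metrics: JetResponseMetrics | None = None,
                        systemic_source: str = "measured") -> EntrainmentResult:
    """Quantify entrainment from a (filtered) record.

    Q_meas,RPA is averaged over the burst injection periods with the
    initial rise transient of each burst excluded (twice the measured rise
    completion when ``rise_metrics`` is given, 1 s otherwise); continuous
    runs are additionally truncated to whole cardiac cycles.  Q_s is the
    measured pre-injection systemic flow by default, or the nominal pump
    output with ``systemic_source="nominal"``.
    """
    period = 60.0 / float(record.metadata.get("heart_rate", 80.0))
    pre = boundaries.pre
    if systemic_source == "nominal":
        hr = float(record.metadata.get("heart_rate", 80.0))
        sv = float(record.metadata.get("stroke_volume", 30.0))
        q_s = hr * sv / 1000.0
    elif systemic_source == "measured":
        q_s = (cycle_average(record, "q_upper", pre)
               + cycle_average(record, "q_lower", pre))
    else:
        raise InvalidParameterError(
            f"systemic_source must be 'measured' or 'nominal', got {systemic_source!r}")

    windows = boundaries.injection_periods or [boundaries.active]
    if rise_metrics is not None and rise_metrics.rise_time is not None:
        exclusion = 2.0 * rise_metrics.rise_time + 0.5
    else:
        exclusion = 1.0

    if protocol.mode == "continuous":
        a, b = windows[0]
        a = min(a + exclusion, b)
        try:
            q_meas = cycle_average(record, "q_rpa", (a, b))
        except InsufficientWindowError:
            q_meas = _plain_mean(record, [(a, b)])
    else:
        plateaus = [(min(a + exclusion, 0.5 * (a + b)), b) for a, b in windows]
        q_meas = _plain_mean(record, plateaus)

    return entrainment_rate(q_meas, baseline_rpa(q_s, pulmonary_split),
                            protocol.rate_l_min, protocol)


def _plain_mean(record: WaveformRecord, windows: list[tuple[float, float]]) -> float:
    t = record.time
    q = record.channel("q_rpa")
    mask = np.zeros_like(t, dtype=bool)
    for a, b in windows:
        mask |= (t >= a) & (t < b)
    if not mask.any():
        raise InsufficientWindowError("measurement windows contain no samples")
    return float(np.mean(q[mask]))


# ---------------------------------------------------------------------------
# sweep matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntrainmentMatrix:
    """Q_ent over the (V_inj x Q_inj) grid of one injection mode.

    ``values`` is indexed by injection volume (L, rows) with injection
    rates (L/min, columns) strictly increasing left to right.
    """

    values: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise IncompleteSweepError(
                f"injection-rate columns must be strictly increasing, got {cols}")

    @property
    def rates(self) -> list[float]:
        return [float(c) for c in self.values.columns]

    @property
    def volumes(self) -> list[float]:
        return [float(r) for r in self.values.index]

    def cell(self, volume: float, rate: float) -> float:
        """Cell lookup tolerant of float-key rounding noise."""
        rows = [v for v in self.values.index
                if np.isclose(float(v), volume, rtol=1e-6, atol=1e-9)]
        cols = [c for c in self.values.columns
                if np.isclose(float(c), rate, rtol=1e-6, atol=1e-9)]
        if not rows or not cols:
            raise IncompleteSweepError(
                f"no cell at V={volume} L, Q={rate} L/min "
                f"(rows {self.volumes}, cols {self.rates})")
        return float(self.values.loc[rows[0], cols[0]])

    def labels(self) -> pd.DataFrame:
        """Green/red semantics: entrainment (Q_ent>0) vs blockage."""
        return self.values.map(
            lambda v: "entrainment" if v > NEUTRAL_DEADBAND
            else "blockage" if v < -NEUTRAL_DEADBAND else "neutral")

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="V_inj_L")


def entrainment_matrix(results: list[EntrainmentResult], mode: str,
                       volume_key: str = "total") -> EntrainmentMatrix:
    """Assemble per-run results into the rectangular sweep matrix.

    ``volume_key`` selects the row coordinate: total injected volume
    (``"total"``) or per-burst volume (``"burst"``, used for pulsed runs).
    Raises :class:`IncompleteSweepError` naming any missing or duplicated
    grid cell.
    """
    cells: dict[tuple[float, float], float] = {}
    for res in results:
        if res.protocol is None:
            raise IncompleteSweepError("result lacks protocol metadata")
        if res.protocol.mode != mode:
            continue
        vol = (res.protocol.total_volume_l if volume_key == "total"
               else res.protocol.burst_volume_ml / 1000.0)
        key = (round(vol, 6), round(res.protocol.rate_l_min, 6))
        if key in cells:
            raise IncompleteSweepError(
                f"duplicate grid cell V={key[0]} L, Q={key[1]} L/min")
        cells[key] = res.q_ent
    if not cells:
        raise IncompleteSweepError(f"no results for mode {mode!r}")
    volumes = sorted({k[0] for k in cells})
    rates = sorted({k[1] for k in cells})
    for v in volumes:
        for r in rates:
            if (v, r) not in cells:
                raise IncompleteSweepError(f"missing grid cell V={v} L, Q={r} L/min")
    df = pd.DataFrame([[cells[(v, r)] for r in rates] for v in volumes],
                      index=volumes, columns=rates)
    return EntrainmentMatrix(df, mode)


def column_normalized_mean(matrix: EntrainmentMatrix, q_inj: float) -> float:
    """Mean of one rate column's Q_ent values divided by that Q_inj."""
    col = _find_column(matrix, q_inj)
    return float(matrix.values[col].mean() / q_inj)


def cutoff_rate(matrix: EntrainmentMatrix) -> float | None:
    """Largest injection rate whose entire column shows entrainment.

    Returns ``None`` (the explicit no-entrainment marker) when no column is
    entirely positive.  Row order is irrelevant.
    """
    best = None
    for col in matrix.values.columns:
        if (matrix.values[col] > 0).all():
            rate = float(col)
            best = rate if best is None else max(best, rate)
    return best


def _find_column(matrix: EntrainmentMatrix, q_inj: float):
    for col in matrix.values.columns:
        if np.isclose(float(col), q_inj, rtol=1e-6, atol=1e-9):
            return col
    raise IncompleteSweepError(
        f"no column for Q_inj = {q_inj} L/min (have {matrix.rates})")
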