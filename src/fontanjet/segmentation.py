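"""Partition an RPA flow waveform into pre / active / post injection stages.

Two modes are provided:

* ``command_aligned`` - boundaries come straight from the injection
  protocol's command schedule (the synthetic-validation path, where the
  command times are known exactly);
* ``signal_detected`` - boundaries are detected from the waveform itself:
  the active stage starts at the first sample exceeding the pre-injection
  mean + k*SD for m consecutive samples and ends when the signal stays
  below that threshold for m samples after the last excursion (for records
  lacking protocol metadata, e.g. digitized rig data).

The active stage of a pulsed run is further split into its five bursts, and
every burst window into (a) the jet injection period and (b) the jet
shutoff period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (BurstCountMismatchError, InsufficientBaselineError,
                     NoInjectionDetectedError, SegmentationError)
from .injection_protocol import InjectionProtocol
from .waveform import WaveformRecord

#: detection threshold in baseline standard deviations
DEFAULT_K = 3.0
#: consecutive supra-threshold samples required (0.1 s at 100 Hz)
DEFAULT_M = 10

Interval = tuple[float, float]


@dataclass
class StageBoundaries:
    """Three-stage partition plus per-burst sub-intervals (times in s)."""

    pre: Interval
    active: Interval
    post: Interval
    burst_windows: list[Interval] = field(default_factory=list)
    injection_periods: list[Interval] = field(default_factory=list)
    shutoff_periods: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.pre[1] == self.active[0] and self.active[1] == self.post[0]):
            raise SegmentationError(
                f"stages must be contiguous: pre={self.pre} active={self.active} "
                f"post={self.post}")
        for a, b in (self.pre, self.active, self.post):
            if b < a:
                raise SegmentationError(f"inverted interval ({a}, {b})")
        for i, w in enumerate(self.burst_windows):
            if w[0] < self.active[0] - 1e-9 or w[1] > self.active[1] + 1e-9:
                raise SegmentationError(f"burst window {w} outside active stage")
            if i and w[0] < self.burst_windows[i - 1][1] - 1e-9:
                raise SegmentationError("burst windows overlap or are unsorted")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"pre": self.pre, "active": self.active, "post": self.post,
               "burst_windows": self.burst_windows,
               "injection_periods": self.injection_periods,
               "shutoff_periods": self.shutoff_periods}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "StageBoundaries":
        doc = json.loads(text)
        return cls(tuple(doc["pre"]), tuple(doc["active"]), tuple(doc["post"]),
                   [tuple(w) for w in doc["burst_windows"]],
                   [tuple(w) for w in doc["injection_periods"]],
                   [tuple(w) for w in doc["shutoff_periods"]])


def _detect_runs(above: np.ndarray, m: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= m, as (start, end) index pairs."""
    runs = []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= m:
            runs.append((int(s), int(e)))
    return runs


def segment_stages(record: WaveformRecord,
                   protocol: InjectionProtocol | None = None,
                   method: str = "command_aligned",
                   k: float = DEFAULT_K, m: int = DEFAULT_M,
                   shutoff_margin: float = 5.0) -> StageBoundaries:
    """Locate the pre / active / post stages of the RPA flow waveform.

    ``shutoff_margin`` extends the active stage past the last command-off
    instant so the wind-down (shutoff period) is analyzed inside stage 2.
    """
    q = record.channel("q_rpa")
    t = record.time
    period = 60.0 / float(record.metadata.get("heart_rate", 80.0))

    if method == "command_aligned":
        if protocol is None:
            raise SegmentationError("command_aligned mode requires a protocol")
        start = protocol.start_time
        end = min(protocol.end_time + shutoff_margin, float(t[-1]))
    elif method == "signal_detected":
        baseline_end = protocol.start_time if protocol is not None else None
        start, end = _detect_active(t, q, k, m, baseline_end)
    else:
        raise SegmentationError(f"unknown segmentation method {method!r}")

    if start - t[0] < period:
        raise InsufficientBaselineError(
            f"pre-injection stage of {start - t[0]:.3g}s is shorter than one "
            f"cardiac cycle ({period:.3g}s)")
    boundaries = StageBoundaries(pre=(float(t[0]), float(start)),
                                 active=(float(start), float(end)),
                                 post=(float(end), float(t[-1])))
    return boundaries


def _detect_active(t: np.ndarray, q: np.ndarray, k: float, m: int,
                   baseline_end: float | None) -> tuple[float, float]:
    """Threshold rule: first/last m-sample excursion above mean + k*SD."""
    if baseline_end is None:
        n_base = max(int(0.25 * t.size), m)
    else:
        n_base = int(np.searchsorted(t, baseline_end))
    base = q[:n_base]
    thr = float(np.mean(base) + k * np.std(base))
    runs = _detect_runs(q > thr, m)
    if not runs:
        raise NoInjectionDetectedError(
            f"no {m}-sample excursion above threshold {thr:.4g}")
    start_idx = runs[0][0]
    last_above = runs[-1][1] - 1  # last supra-threshold sample of last run
    end_idx = min(last_above + m, t.size - 1)
    return float(t[start_idx]), float(t[end_idx])


def segment_bursts(boundaries: StageBoundaries, record: WaveformRecord,
                   n_bursts: int,
                   protocol: InjectionProtocol | None = None,
                   method: str = "command_aligned",
                   k: float = DEFAULT_K, m: int = DEFAULT_M) -> StageBoundaries:
    """Split the active stage into burst windows and their sub-periods.

    Each burst window runs from its activation to the start of the next
    burst (or the end of the active stage) and is split into the injection
    period (command on) and the shutoff period (wind-down) at the
    command-off instant (``command_aligned``) or the last supra-threshold
    sample (``signal_detected``).
    """
    if n_bursts < 1:
        raise SegmentationError("n_bursts must be >= 1")
    t0, t1 = boundaries.active

    if method == "command_aligned":
        if protocol is None:
            raise SegmentationError("command_aligned mode requires a protocol")
        if protocol.burst_count != n_bursts:
            raise BurstCountMismatchError(n_bursts, protocol.burst_count)
        commands = protocol.command_windows()
    elif method == "signal_detected":
        q = record.channel("q_rpa")
        t = record.time
        mask = (t >= t0) & (t <= t1)
        ta, qa = t[mask], q[mask]
        pre_mask = t < t0
        if not pre_mask.any():
            raise SegmentationError("no pre-injection samples for the threshold")
        thr = float(np.mean(q[pre_mask]) + k * np.std(q[pre_mask]))
        runs = _detect_runs(qa > thr, m)
        if len(runs) != n_bursts:
            raise BurstCountMismatchError(n_bursts, len(runs))
        commands = [(float(ta[s]), float(ta[e - 1])) for s, e in runs]
    else:
        raise SegmentationError(f"unknown segmentation method {method!r}")

    windows: list[Interval] = []
    injection: list[Interval] = []
    shutoff: list[Interval] = []
    for i, (on, off) in enumerate(commands):
        nxt = commands[i + 1][0] if i + 1 < len(commands) else t1
        on_c = float(np.clip(on, t0, t1))
        off_c = float(np.clip(off, t0, t1))
        nxt_c = float(np.clip(nxt, t0, t1))
        if off_c <= on_c or nxt_c <= off_c:
            raise BurstCountMismatchError(n_bursts, i)
        windows.append((on_c, nxt_c))
        injection.append((on_c, off_c))
        shutoff.append((off_c, nxt_c))
    boundaries.burst_windows = windows
    boundaries.injection_periods = injection
    boundaries.shutoff_periods = shutoff
    boundaries.__post_init__()  # re-validate with the new windows
    return boundaries
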