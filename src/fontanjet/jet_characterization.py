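"""Step-response metrics of the RPA flow during jet activation and shutoff.

The injection does not take effect instantaneously: the jet spools up,
possibly overshoots, and converges to a steady settling value.  This module
quantifies that response with the standard step-response vocabulary:

* rise time - time from 10% to 90% of the response amplitude
  Delta = settling_value - baseline during activation;
* fall time - the mirror process during shutoff (90% -> 10% of the same
  Delta below the settling value);
* settling time - time from activation until the signal stays within a
  2% * Delta band around the settling value;
* overshoot / undershoot - peak excursions beyond the settling value,
  as a percentage of Delta;
* jet relaxation time - t_rel = t_rise - t_fall.  A positive t_rel means
  the co-flow takes longer to plateau than to dissipate the jet effect
  (low likelihood of downstream fluid buildup); a negative t_rel flags
  buildup risk across repeated pulses.

Crossing times are located by linear interpolation between bracketing
samples, giving sub-sample resolution; the first-crossing convention is
used when oscillation produces multiple crossings.  The settling value is
the mean of the final quartile of the activation segment.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, MalformedSegmentError, NoResponseError

#: fraction of the activation segment used for the settling value
SETTLING_FRACTION = 0.25
#: settling band half-width as a fraction of the response amplitude
SETTLING_BAND = 0.02


@dataclass(frozen=True)
class JetResponseMetrics:
    """Step-response summary of one activation/shutoff pair (or burst).

    Amplitudes in L/min, times in seconds.  ``relaxation_time`` is
    ``rise_time - fall_time`` whenever both are present.
    """

    baseline_value: float | None = None
    peak_value: float | None = None
    peak_time: float | None = None
    settling_value: float | None = None
    settling_time: float | None = None
    settling_min: float | None = None
    settling_max: float | None = None
    overshoot_pct: float | None = None
    undershoot_pct: float | None = None
    rise_time: float | None = None
    fall_time: float | None = None

    @property
    def relaxation_time(self) -> float | None:
        if self.rise_time is None or self.fall_time is None:
            return None
        return self.rise_time - self.fall_time


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float,
                    direction: str) -> float | None:
    """Time of the first up/down crossing of ``level``, linearly interpolated."""
    if direction == "up":
        hit = (y[:-1] < level) & (y[1:] >= level)
        if y[0] >= level:
            return float(t[0])
    else:
        hit = (y[:-1] > level) & (y[1:] <= level)
        if y[0] <= level:
            return float(t[0])
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return None
    i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def rise_metrics(t: Sequence[float], y: Sequence[float],
                 baseline_value: float) -> JetResponseMetrics:
    """Characterize the activation (injection-period) segment.

    ``t``/``y`` start at command activation; ``baseline_value`` is the
    pre-injection mean flow.  Raises :class:`NoResponseError` when the
    settling value does not exceed the baseline, and
    :class:`MalformedSegmentError` when the 10%/90% crossings are absent.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        raise MalformedSegmentError("activation segment too short")
    n_tail = max(int(round(SETTLING_FRACTION * t.size)), 1)
    settling_value = float(np.mean(y[-n_tail:]))
    delta = settling_value - baseline_value
    if delta <= 0:
        raise NoResponseError(
            f"no positive response: settling {settling_value:.4g} <= "
            f"baseline {baseline_value:.4g}")
    t10 = _first_crossing(t, y, baseline_value + 0.1 * delta, "up")
    t90 = _first_crossing(t, y, baseline_value + 0.9 * delta, "up")
    if t10 is None or t90 is None:
        raise MalformedSegmentError("10%/90% rise crossings not found")

    post = y[t >= t10]
    t_post = t[t >= t10]
    peak_idx = int(np.argmax(post))
    peak_value = float(post[peak_idx])
    peak_time = float(t_post[peak_idx])
    settling_min = float(np.min(post))
    settling_max = float(np.max(post))
    overshoot = 100.0 * max(peak_value - settling_value, 0.0) / delta

    # undershoot: dips below the settling value after it is first reached
    t_settle_cross = _first_crossing(t, y, settling_value, "up")
    if t_settle_cross is None:
        undershoot = 0.0
    else:
        after = y[t >= t_settle_cross]
        undershoot = 100.0 * max(settling_value - float(np.min(after)), 0.0) / delta

    band = SETTLING_BAND * abs(delta)
    outside = np.abs(y - settling_value) > band
    if outside.any():
        last_out = int(np.flatnonzero(outside)[-1])
        settling_time = (float(t[last_out + 1] - t[0]) if last_out + 1 < t.size
                         else float(t[-1] - t[0]))
    else:
        settling_time = 0.0

    return JetResponseMetrics(
        baseline_value=float(baseline_value), peak_value=peak_value,
        peak_time=peak_time, settling_value=settling_value,
        settling_time=settling_time, settling_min=settling_min,
        settling_max=settling_max, overshoot_pct=overshoot,
        undershoot_pct=undershoot, rise_time=float(t90 - t10))


def fall_metrics(t: Sequence[float], y: Sequence[float], baseline_value: float,
                 settling_value: float) -> JetResponseMetrics:
    """Characterize the shutoff segment (mirror of :func:`rise_metrics`).

    ``t``/``y`` start at command shutoff; ``settling_value`` comes from the
    preceding activation segment, and the same response amplitude
    Delta = settling - baseline defines the 90%/10% levels.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        raise MalformedSegmentError("shutoff segment too short")
    delta = settling_value - baseline_value
    if delta <= 0:
        raise NoResponseError(
            f"no positive response amplitude: delta {delta:.4g} <= 0")
    t10 = _first_crossing(t, y, settling_value - 0.1 * delta, "down")
    t90 = _first_crossing(t, y, settling_value - 0.9 * delta, "down")
    if t10 is None or t90 is None:
        raise MalformedSegmentError(
            "segment never decays through the 10%/90% fall levels")
    return JetResponseMetrics(baseline_value=float(baseline_value),
                              settling_value=float(settling_value),
                              fall_time=float(t90 - t10))


def relaxation_time(rise: JetResponseMetrics,
                    fall: JetResponseMetrics) -> tuple[float, str]:
    """Jet relaxation time t_rel = t_rise - t_fall, with a buildup label.

    Returns ``(t_rel, label)`` where the label is ``"no-buildup"`` for
    t_rel > 0, ``"buildup-risk"`` for t_rel < 0 and ``"boundary"`` at 0.
    """
    if rise.rise_time is None or fall.fall_time is None:
        raise EmptyInputError("both rise and fall metrics are required")
    t_rel = rise.rise_time - fall.fall_time
    label = ("no-buildup" if t_rel > 0
             else "buildup-risk" if t_rel < 0 else "boundary")
    return t_rel, label


def combine(rise: JetResponseMetrics, fall: JetResponseMetrics) -> JetResponseMetrics:
    """Merge activation metrics with the shutoff fall time into one record."""
    return replace(rise, fall_time=fall.fall_time)


def pulsed_summary(per_burst: Sequence[JetResponseMetrics]) -> JetResponseMetrics:
    """Field-wise arithmetic mean across the bursts of a pulsed sequence."""
    if len(per_burst) == 0:
        raise EmptyInputError("no burst metrics to summarize")
    out: dict[str, float | None] = {}
    for f in fields(JetResponseMetrics):
        vals = [getattr(m, f.name) for m in per_burst]
        present = [v for v in vals if v is not None]
        out[f.name] = float(np.mean(present)) if present else None
    return JetResponseMetrics(**out)
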