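"""Uniformly sampled multichannel flow/pressure records and their CSV dialect.

A :class:`WaveformRecord` is the lingua franca between the simulator, the
filter stages, the segmenter and the entrainment analysis.  Flow channels
(``q_*``) are in L/min, pressure channels (``p_*``) in mmHg, time in seconds.

CSV contract
------------
Header lines beginning ``#`` carry ``key=value`` metadata; the first data
column is ``time_s`` and the remaining columns are channel names.  Floats are
written with 17 significant digits so a write/read round-trip is lossless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

#: canonical channel names and units
FLOW_CHANNELS = ("q_upper", "q_lower", "q_rpa", "q_lpa")
PRESSURE_CHANNELS = ("p_upper", "p_lower", "p_rpa", "p_lpa", "p_aortic")
CHANNEL_UNITS = {**{c: "L/min" for c in FLOW_CHANNELS},
                 **{c: "mmHg" for c in PRESSURE_CHANNELS}}

_MAGIC = "fontanjet-waveform v1"


@dataclass
class WaveformRecord:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    time:
        Strictly increasing, uniformly spaced sample times in seconds.
    channels:
        Mapping channel name -> samples; every channel has the same length
        as ``time``.
    sampling_rate:
        Samples per second; must be consistent with ``time``.
    metadata:
        Free-form provenance (pump settings, protocol case, seed, ...).
        The key ``provenance`` is one of ``simulated | filtered | external``.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    sampling_rate: float
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.time.ndim != 1 or self.time.size < 2:
            raise FormatError("time vector must be 1-D with at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise FormatError("time vector must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError("time vector is not uniform (gap or jitter detected)")
        n = self.time.size
        for name, x in self.channels.items():
            if x.shape != (n,):
                raise FormatError(f"channel {name!r} length {x.size} != time length {n}")
        expected = (n - 1) / (self.time[-1] - self.time[0])
        if not np.isclose(expected, self.sampling_rate, rtol=1e-6):
            raise FormatError(
                f"sampling_rate {self.sampling_rate} inconsistent with time vector "
                f"(implied {expected:.6g})")

    # -- convenience ------------------------------------------------------
    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise FormatError(f"record has no channel {name!r}") from None

    def slice(self, t0: float, t1: float) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Return (time, channels) restricted to t0 <= t < t1."""
        mask = (self.time >= t0 - 1e-12) & (self.time < t1 - 1e-12)
        return self.time[mask], {k: v[mask] for k, v in self.channels.items()}

    def copy_with(self, channels: Mapping[str, np.ndarray] | None = None,
                  **meta: object) -> "WaveformRecord":
        ch = dict(self.channels if channels is None else channels)
        md = {**self.metadata, **meta}
        return WaveformRecord(self.time.copy(), {k: np.array(v) for k, v in ch.items()},
                              self.sampling_rate, md)


def write_waveform_csv(record: WaveformRecord, path: str | Path) -> None:
    """Serialize a record to the package CSV dialect (lossless round-trip)."""
    record.validate()
    buf = io.StringIO()
    buf.write(f"# {_MAGIC}\n")
    buf.write(f"# sampling_rate={record.sampling_rate!r}\n")
    for key in sorted(record.metadata):
        val = record.metadata[key]
        buf.write(f"# {key}={val!r}\n" if isinstance(val, float) else f"# {key}={val}\n")
    df = pd.DataFrame({"time_s": record.time, **record.channels})
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_waveform_csv(path: str | Path) -> WaveformRecord:
    """Parse a record written by :func:`write_waveform_csv`.

    Raises :class:`FormatError` naming the defect for missing/duplicate
    channel columns or a non-uniform time vector.
    """
    text = Path(path).read_text().splitlines()
    metadata: dict[str, object] = {}
    sampling_rate = None
    data_start = 0
    for i, line in enumerate(text):
        if not line.startswith("#"):
            data_start = i
            break
        body = line[1:].strip()
        if body == _MAGIC:
            continue
        if "=" not in body:
            raise FormatError(f"malformed metadata line: {line!r}")
        key, _, val = body.partition("=")
        key, val = key.strip(), val.strip()
        parsed: object = val
        try:
            parsed = int(val)
        except ValueError:
            try:
                parsed = float(val)
            except ValueError:
                pass
        if key == "sampling_rate":
            sampling_rate = float(parsed)  # type: ignore[arg-type]
        else:
            metadata[key] = parsed
    if sampling_rate is None:
        raise FormatError("missing sampling_rate metadata header")

    header = [h.strip() for h in text[data_start].split(",")]
    if header[0] != "time_s":
        raise FormatError("first data column must be 'time_s'")
    names = header[1:]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"duplicate channel column(s): {sorted(dupes)}")
    if not names:
        raise FormatError("no channel columns present")

    df = pd.read_csv(io.StringIO("\n".join(text[data_start:])),
                     float_precision="round_trip")
    return WaveformRecord(df["time_s"].to_numpy(),
                          {n: df[n].to_numpy() for n in names},
                          sampling_rate, metadata)
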