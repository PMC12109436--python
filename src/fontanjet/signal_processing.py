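"""Two-stage denoising of raw rig waveforms.

Stage 1 is a zero-phase (forward-backward) Butterworth low-pass that removes
broadband sensor noise and mains interference; stage 2 is a Savitzky-Golay
polynomial smoother that polishes the waveform shape.  Both stages preserve
DC exactly / to high accuracy, and the forward-backward application keeps
rise/fall timing metrics free of phase distortion.

Defaults: order 4, 15 Hz cutoff (~11x the 80 bpm heart frequency, so cardiac
harmonics pass), SG window 21 samples, polynomial order 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .errors import ConfigError, FormatError
from .waveform import WaveformRecord


@dataclass(frozen=True)
class FilterConfig:
    butterworth_order: int = 4
    butterworth_cutoff: float = 15.0  # Hz
    sg_window: int = 21               # samples, odd
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.butterworth_order < 1:
            raise ConfigError("butterworth_order must be >= 1")
        if self.butterworth_cutoff <= 0:
            raise ConfigError("butterworth_cutoff must be > 0")
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise ConfigError("sg_window must be odd and >= 3")
        if self.sg_polyorder >= self.sg_window:
            raise ConfigError("sg_polyorder must be < sg_window")


def butterworth_lowpass(signal: np.ndarray, sampling_rate: float,
                        config: FilterConfig = FilterConfig()) -> np.ndarray:
    """Zero-phase Butterworth low-pass; DC gain exactly 1."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FormatError("signal contains non-finite samples")
    if config.butterworth_cutoff >= sampling_rate / 2.0:
        raise ConfigError(
            f"cutoff {config.butterworth_cutoff} Hz >= Nyquist "
            f"({sampling_rate / 2.0} Hz)")
    sos = butter(config.butterworth_order, config.butterworth_cutoff,
                 btype="low", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, x)


def savitzky_golay(signal: np.ndarray,
                   config: FilterConfig = FilterConfig()) -> np.ndarray:
    """Local least-squares polynomial smoothing.

    Polynomials of degree <= ``sg_polyorder`` are reproduced exactly in the
    interior of the signal.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < config.sg_window:
        raise ConfigError(
            f"signal length {x.size} shorter than SG window {config.sg_window}")
    return savgol_filter(x, config.sg_window, config.sg_polyorder, mode="interp")


def filter_record(record: WaveformRecord,
                  config: FilterConfig = FilterConfig()) -> WaveformRecord:
    """Apply Butterworth then Savitzky-Golay to every channel.

    Returns a new record with provenance ``"filtered"``; per-channel errors
    are re-raised with the channel name attached.
    """
    out: dict[str, np.ndarray] = {}
    for name, x in record.channels.items():
        if x.size == 0:
            raise FormatError(f"channel {name!r} is empty")
        try:
            y = butterworth_lowpass(x, record.sampling_rate, config)
            y = savitzky_golay(y, config)
        except (ConfigError, FormatError) as exc:
            raise type(exc)(f"channel {name!r}: {exc}") from exc
        out[name] = y
    return record.copy_with(channels=out, provenance="filtered")
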