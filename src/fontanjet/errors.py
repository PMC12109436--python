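"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`FontanJetError`
so callers (notably the sweep driver, which must keep going when a single
trial fails) can catch one base class.
"""


class FontanJetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FontanJetError, ValueError):
    """A model parameter violates its physical or numeric constraints."""


class NumericStateError(FontanJetError, ValueError):
    """NaN/inf encountered in the solver state."""


class ConvergenceError(FontanJetError, RuntimeError):
    """Periodic steady state was not reached within the settle window."""


class TuningError(FontanJetError, RuntimeError):
    """Resistance tuning root search failed to converge."""


class InvalidTargetError(FontanJetError, ValueError):
    """A flow-split target lies outside (0, 1)."""


class InvalidProtocolError(FontanJetError, ValueError):
    """An injection protocol violates the injector's admissible envelope."""


class InsufficientWindowError(FontanJetError, ValueError):
    """Averaging window shorter than one cardiac cycle."""


class AliasingError(FontanJetError, ValueError):
    """Sensor sampling rate cannot represent the cardiac waveform."""


class FormatError(FontanJetError, ValueError):
    """A waveform file or record violates the CSV/record contract."""


class ConfigError(FontanJetError, ValueError):
    """A filter or analysis configuration is inconsistent."""


class SegmentationError(FontanJetError, RuntimeError):
    """Base class for stage/burst segmentation failures."""


class NoInjectionDetectedError(SegmentationError):
    """No supra-threshold excursion found in signal-detected mode."""


class InsufficientBaselineError(SegmentationError):
    """Pre-injection stage shorter than one cardiac cycle."""


class BurstCountMismatchError(SegmentationError):
    """Number of detected bursts differs from the expected count."""

    def __init__(self, expected: int, found: int):
        super().__init__(f"expected {expected} burst(s), found {found}")
        self.expected = expected
        self.found = found


class NoResponseError(FontanJetError, ValueError):
    """Response amplitude above baseline is non-positive."""


class MalformedSegmentError(FontanJetError, ValueError):
    """A rise/fall segment lacks the threshold crossings required."""


class EmptyInputError(FontanJetError, ValueError):
    """An aggregate operation received no inputs."""


class UndefinedNormalizationError(FontanJetError, ZeroDivisionError):
    """Normalized entrainment requested with zero injection rate."""


class AlignmentError(FontanJetError, ValueError):
    """Two series do not share a time base."""


class IncompleteSweepError(FontanJetError, ValueError):
    """A (V_inj, Q_inj) grid cell is missing or duplicated."""
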