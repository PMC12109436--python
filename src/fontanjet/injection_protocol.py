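"""Clinical injection protocol: the 20-case continuous/pulsed parameter space.

The angiographic injector delivers either one long continuous injection or a
five-burst pulsed sequence at a commanded syringe rate.  Commands are
rectangular; the physical jet spools up and down with a first-order lag
(``injector_time_constant``), which is volume-conserving in the long-time
limit.  Rates are specified in mL/s on the pump interface; flows are exposed
in L/min (1 mL/s = 0.06 L/min).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidProtocolError

#: admissible syringe rate envelope of the injector, mL/s
RATE_MIN_ML_S = 0.3
RATE_MAX_ML_S = 50.0

ML_S_TO_L_MIN = 0.06


@dataclass(frozen=True)
class InjectionProtocol:
    """One row of the injection protocol table.

    Parameters
    ----------
    case_id:
        Case number (1..20 in the standard table; 0 for ad-hoc protocols).
    mode:
        ``"continuous"`` (single long injection) or ``"pulsed"``
        (five-burst sequence).
    rate_ml_s:
        Commanded syringe rate, mL/s; must lie in [0.3, 50].
    burst_count:
        1 for continuous, 5 for pulsed.
    burst_volume_ml:
        Volume per burst, mL; total volume = burst_count * burst_volume_ml.
    inter_burst_gap:
        Quiet interval between consecutive bursts, s.
    start_time:
        Command-on time of the first burst, s into the record (after the
        circulation model has settled to periodicity).
    injector_time_constant:
        First-order spool-up/down lag, s; 0 disables the lag.
    """

    case_id: int
    mode: str
    rate_ml_s: float
    burst_count: int
    burst_volume_ml: float
    inter_burst_gap: float = 5.0
    start_time: float = 15.0
    injector_time_constant: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "pulsed"):
            raise InvalidProtocolError(f"unknown mode {self.mode!r}")
        if not RATE_MIN_ML_S <= self.rate_ml_s <= RATE_MAX_ML_S:
            raise InvalidProtocolError(
                f"rate {self.rate_ml_s} mL/s outside injector range "
                f"[{RATE_MIN_ML_S}, {RATE_MAX_ML_S}]")
        if self.mode == "continuous" and self.burst_count != 1:
            raise InvalidProtocolError("continuous mode requires burst_count=1")
        if self.mode == "pulsed" and self.burst_count != 5:
            raise InvalidProtocolError("pulsed mode requires burst_count=5")
        if self.burst_volume_ml < 0:
            raise InvalidProtocolError("burst volume must be >= 0")
        if self.injector_time_constant < 0 or self.inter_burst_gap < 0:
            raise InvalidProtocolError("lag and gap must be >= 0")

    # -- derived quantities ----------------------------------------------
    @property
    def rate_l_min(self) -> float:
        """Commanded rate in L/min."""
        return self.rate_ml_s * ML_S_TO_L_MIN

    @property
    def burst_duration(self) -> float:
        """Command-on duration of one burst, s."""
        return self.burst_volume_ml / self.rate_ml_s

    @property
    def total_volume_l(self) -> float:
        return injected_volume(self)

    def command_windows(self) -> list[tuple[float, float]]:
        """[(on, off), ...] command intervals of each burst, in seconds."""
        out = []
        t = self.start_time
        for _ in range(self.burst_count):
            out.append((t, t + self.burst_duration))
            t += self.burst_duration + self.inter_burst_gap
        return out

    @property
    def end_time(self) -> float:
        """Command-off time of the last burst."""
        return self.command_windows()[-1][1]

    def with_timing(self, start_time: float | None = None,
                    injector_time_constant: float | None = None,
                    inter_burst_gap: float | None = None) -> "InjectionProtocol":
        kw = {}
        if start_time is not None:
            kw["start_time"] = start_time
        if injector_time_constant is not None:
            kw["injector_time_constant"] = injector_time_constant
        if inter_burst_gap is not None:
            kw["inter_burst_gap"] = inter_burst_gap
        return replace(self, **kw)


def protocol_table(**timing: float) -> list[InjectionProtocol]:
    """The full 20-case protocol: 8 pulsed then 12 continuous cases.

    Pulsed cases sweep rates {5, 10, 15, 20} mL/s x burst volumes {20, 15} mL
    (five bursts each); continuous cases sweep the same rates x total volumes
    {50, 100, 150} mL.  Keyword arguments (``start_time``,
    ``injector_time_constant``, ``inter_burst_gap``) override the timing
    defaults uniformly.
    """
    cases: list[InjectionProtocol] = []
    cid = 1
    for rate in (5.0, 10.0, 15.0, 20.0):
        for vol in (20.0, 15.0):
            cases.append(InjectionProtocol(cid, "pulsed", rate, 5, vol, **timing))
            cid += 1
    for rate in (5.0, 10.0, 15.0, 20.0):
        for vol in (50.0, 100.0, 150.0):
            cases.append(InjectionProtocol(cid, "continuous", rate, 1, vol, **timing))
            cid += 1
    return cases


def get_case(case_id: int, **timing: float) -> InjectionProtocol:
    """Look up one protocol case by its table number (1-20)."""
    for proto in protocol_table(**timing):
        if proto.case_id == case_id:
            return proto
    raise InvalidProtocolError(f"no such case id {case_id} (valid: 1-20)")


def injected_volume(protocol: InjectionProtocol) -> float:
    """Total commanded volume in litres: burst_count x burst_volume."""
    return protocol.burst_count * protocol.burst_volume_ml / 1000.0


def _first_order_lag(t: np.ndarray, windows: list[tuple[float, float]],
                     height: float, tau: float) -> np.ndarray:
    """Exact response of a unit first-order lag to a train of rectangles.

    Superposition of step responses: each window (a, b) contributes
    height * [s(t-a) - s(t-b)] with s(x) = (1 - exp(-x/tau)) * 1[x>0].
    """
    y = np.zeros_like(t)
    for a, b in windows:
        xa = t - a
        xb = t - b
        y += height * np.where(xa > 0, 1.0 - np.exp(-np.maximum(xa, 0.0) / tau), 0.0)
        y -= height * np.where(xb > 0, 1.0 - np.exp(-np.maximum(xb, 0.0) / tau), 0.0)
    return y


def injection_flow(t, protocol: InjectionProtocol) -> np.ndarray | float:
    """Delivered injection flow at time(s) ``t``, L/min.

    The rectangular command (height = commanded rate, width = burst
    duration, repeated per burst) is passed through the injector's
    first-order lag.  With zero lag the command itself is returned.
    """
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    windows = protocol.command_windows()
    height = protocol.rate_l_min
    if protocol.injector_time_constant == 0.0:
        y = np.zeros_like(arr)
        for a, b in windows:
            y += np.where((arr >= a) & (arr < b), height, 0.0)
    else:
        y = _first_order_lag(arr, windows, height, protocol.injector_time_constant)
    return float(y[0]) if scalar else y
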