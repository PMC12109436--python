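"""Published benchtop result matrices, packaged as reference fixtures.

These are the experimentally measured entrainment rates (L/min) and jet
relaxation times (s) over the (injection volume x injection rate) grid, for
continuous and pulsed injections.  They serve two purposes: summary
statistics (column-normalized means, cutoff rates) are verified against
them, and the synthetic rig emulator uses the entrainment values as the
programmed ground truth when sweeping the standard protocol.

Row labels are kept exactly as published.  For the pulsed tables the rows
are labelled 0.015 and 0.2: these correspond to the 5 x 15 cc and 5 x 20 cc
burst sequences respectively (i.e. per-burst volumes of 0.015 L and
0.020 L; the published "0.2" label carries a dropped digit).  Columns are
injection rates in L/min.
"""

from __future__ import annotations

import pandas as pd

from .entrainment import EntrainmentMatrix

_RATES = [0.3, 0.6, 0.9, 1.2]

#: entrainment rate Q_ent [L/min], continuous injections (rows: V_inj, L)
CONTINUOUS_ENTRAINMENT = pd.DataFrame(
    [[0.1646, 0.0015, -0.1084, -0.2263],
     [0.2125, 0.0389, -0.086, -0.2265],
     [0.1985, 0.0144, -0.0866, -0.2454]],
    index=[0.05, 0.1, 0.15], columns=_RATES)

#: entrainment rate Q_ent [L/min], pulsed injections (rows as published)
PULSED_ENTRAINMENT = pd.DataFrame(
    [[0.04412, -0.14936, -0.4581, -0.7167],
     [0.04964, -0.1353, -0.33948, -0.60956]],
    index=[0.015, 0.2], columns=_RATES)

#: jet relaxation time t_rel [s], continuous injections
CONTINUOUS_RELAXATION = pd.DataFrame(
    [[0.497, 0.891, 0.398, 0.198],
     [0.103, 0.100, 0.509, 0.504],
     [0.495, 0.607, 0.399, 0.107]],
    index=[0.05, 0.1, 0.15], columns=_RATES)

#: jet relaxation time t_rel [s], pulsed injections (rows as published)
PULSED_RELAXATION = pd.DataFrame(
    [[0.715, 0.341, 0.118, 0.151],
     [0.196, 0.315, 0.809, 0.021]],
    index=[0.015, 0.2], columns=_RATES)


def continuous_entrainment_matrix() -> EntrainmentMatrix:
    return EntrainmentMatrix(CONTINUOUS_ENTRAINMENT.copy(), "continuous")


def pulsed_entrainment_matrix() -> EntrainmentMatrix:
    return EntrainmentMatrix(PULSED_ENTRAINMENT.copy(), "pulsed")


def reference_entrainment(mode: str, rate_l_min: float,
                          total_volume_l: float, burst_volume_l: float) -> float:
    """Measured Q_ent for one protocol case (emulator ground-truth lookup).

    Continuous rows are keyed by total volume; pulsed rows by per-burst
    volume (0.015 L -> published row 0.015, 0.020 L -> published row 0.2).
    """
    if mode == "continuous":
        return float(CONTINUOUS_ENTRAINMENT.loc[round(total_volume_l, 6),
                                                round(rate_l_min, 6)])
    row = 0.015 if abs(burst_volume_l - 0.015) < 1e-9 else 0.2
    return float(PULSED_ENTRAINMENT.loc[row, round(rate_l_min, 6)])
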