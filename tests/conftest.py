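"""Shared fixtures: tuned parameters and cached synthetic records.

Simulations are cheap (<1 s each) but several tests share the same record,
so the expensive composites are session-scoped.
"""

import numpy as np
import pytest

from fontanjet import (SimulationConfig, default_parameters, get_case,
                       simulate)
from fontanjet.reporting import default_emulation_for_case
from fontanjet.synthetic_mfl import EntrainmentEmulation, compose_noiseless


@pytest.fixture(scope="session")
def params():
    """Packaged tuned rig parameters (80 bpm, 30 cc, 30/70 + 50/50 splits)."""
    return default_parameters()


@pytest.fixture(scope="session")
def baseline_record(params):
    """20 s periodic steady-state run without injection, 100 Hz."""
    return simulate(params, None, SimulationConfig(duration=20.0))


@pytest.fixture(scope="session")
def settle_window(params):
    """Measurement window after the settle cycles of ``baseline_record``."""
    return (10 * params.pump.period, 20.0)


@pytest.fixture(scope="session")
def case12_protocol():
    """Continuous 10 cc/s x 50 cc: the shortest continuous case."""
    return get_case(12)


@pytest.fixture(scope="session")
def case12_clean(params, case12_protocol):
    """Noise-free composite record for case 12 with its published E0."""
    emu = default_emulation_for_case(case12_protocol)
    return compose_noiseless(params, case12_protocol, emu)


@pytest.fixture(scope="session")
def recovery_clean(params):
    """High-rate continuous composite used for noisy parameter recovery.

    At 1.2 L/min injection the default sensor noise (0.05 L/min) is about
    4% of Q_inj, the regime in which plateau/timing recovery is meaningful.
    """
    protocol = get_case(19)  # continuous, 20 cc/s, 100 cc
    emu = EntrainmentEmulation(magnitude=0.2, tau_rise=0.5, tau_fall=0.1)
    return protocol, emu, compose_noiseless(params, protocol, emu)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
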