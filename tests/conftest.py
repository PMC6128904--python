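"""Shared synthetic-session fixtures.

Sessions are generated once per test run at the study conditions the
analyses were designed for (see :mod:`thetalab.presets`): a treadmill
recording at 10 cm/s with a stimulation-gated theta2, and a circular-arena
recording with zone-dependent running speeds and a zone-gated theta2.
"""

import pytest

from thetalab.presets import arena_condition, pac_condition, treadmill_condition
from thetalab.synth import OscillatorSpec, SessionConfig, UnitSpec, generate_session

make_treadmill_config = treadmill_condition
make_arena_config = arena_condition
make_pac_config = pac_condition


@pytest.fixture(scope="session")
def treadmill_session():
    return generate_session(treadmill_condition())


@pytest.fixture(scope="session")
def arena_session():
    return generate_session(arena_condition())


@pytest.fixture(scope="session")
def pac_session():
    return generate_session(pac_condition())


@pytest.fixture(scope="session")
def coupled_unit_session():
    """High-rate unit phase-locked to an 8 Hz theta for |R| recovery."""
    cfg = SessionConfig(
        duration=120.0,
        n_channels=1,
        noise_amplitude=0.0,
        seed=7,
        oscillators=[OscillatorSpec("theta", 8.0, 0.0, 0.1)],
        units=[
            UnitSpec("coupled", mean_rate=100.0, coupling_strength=0.6,
                     phase_source="theta"),
            UnitSpec("uncoupled", mean_rate=100.0, coupling_strength=0.0),
        ],
        trajectory_model="treadmill",
        treadmill_speed=0.0,
    )
    return generate_session(cfg)
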