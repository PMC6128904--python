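"""Canonical study-condition session configurations.

These presets encode the experimental conditions the analyses were designed
around, so that tests, scripts and examples all run against the same
synthetic ground truth:

- ``treadmill_condition``: running at 10 cm/s with a 7.9 Hz theta1 and a
  stimulation-gated 6.8 Hz theta2 during the second half of the session;
- ``arena_condition``: a circular arena with concentric zones, slow
  (~7 cm/s) wall-hugging movement showing a 7.3 Hz theta1 and fast
  (~25 cm/s) inner-zone running where theta1 reaches 9.5 Hz next to a
  zone-gated ~8 Hz theta2;
- ``pac_condition``: a 7 Hz theta whose phase modulates ~70 Hz gamma.

The speed-frequency couplings follow the single linear law
``f = base + slope * speed`` fitted through the two (speed, frequency)
operating points of each condition.
"""

from __future__ import annotations

from .behavior import ArenaSpec
from .synth import OscillatorSpec, PACSpec, SessionConfig

__all__ = ["treadmill_condition", "arena_condition", "pac_condition"]

#: theta1 7.9 Hz and theta2 6.8 Hz at the 10 cm/s treadmill speed
TREADMILL_THETA1 = dict(base_freq=6.9, speed_slope=0.1)
TREADMILL_THETA2 = dict(base_freq=6.3, speed_slope=0.05)

#: theta1 7.3 Hz at 7 cm/s rising to 9.5 Hz at 25 cm/s
ARENA_SLOPE = (9.5 - 7.3) / (25.0 - 7.0)
ARENA_BASE = 7.3 - ARENA_SLOPE * 7.0


def treadmill_condition(seed: int = 1, duration: float = 120.0,
                        stim: bool = True) -> SessionConfig:
    """Treadmill session at 10 cm/s; optional stimulation second half."""
    return SessionConfig(
        duration=duration,
        n_channels=2,
        noise_amplitude=0.02,
        seed=seed,
        oscillators=[
            OscillatorSpec("theta1", amplitude=0.1, **TREADMILL_THETA1),
            OscillatorSpec("theta2", amplitude=0.1, gate="stim_on",
                           **TREADMILL_THETA2),
        ],
        trajectory_model="treadmill",
        treadmill_speed=10.0,
        stim_epochs=[(duration / 2, duration, 16.0)] if stim else [],
    )


def arena_condition(seed: int = 1, duration: float = 300.0) -> SessionConfig:
    """Predator-odor-arena-like session: wall-biased random walk with
    zone-dependent speeds and a zone-gated theta2 in the inner zones."""
    return SessionConfig(
        duration=duration,
        n_channels=2,
        noise_amplitude=0.02,
        seed=seed,
        arena=ArenaSpec(),
        trajectory_model="random_walk_in_arena",
        wall_bias=0.6,
        speed_by_zone={"Wall": 7.0, "Intermediate": 25.0, "Center": 25.0},
        oscillators=[
            OscillatorSpec("theta1", ARENA_BASE, ARENA_SLOPE, 0.1),
            OscillatorSpec("theta2", 6.0, 0.08, 0.1, gate="zone_set",
                           zones=("Intermediate", "Center")),
        ],
    )


def pac_condition(seed: int = 1, duration: float = 120.0,
                  depth: float = 0.8, amp_freq: float = 70.0) -> SessionConfig:
    """Stationary 7 Hz theta phase-modulating narrow-band gamma."""
    return SessionConfig(
        duration=duration,
        n_channels=1,
        noise_amplitude=0.02,
        seed=seed,
        oscillators=[OscillatorSpec("theta", 7.0, 0.0, 0.1)],
        pac=[PACSpec("theta", amp_freq, modulation_depth=depth, amplitude=0.05)],
        trajectory_model="treadmill",
        treadmill_speed=0.0,
    )
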