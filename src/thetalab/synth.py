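"""Synthetic recording sessions with the statistical structure of ventral
hippocampal LFP experiments.

A session combines:

- multi-channel laminar LFP: 1/f background noise plus a sum of gated
  oscillators whose instantaneous frequency tracks running speed
  (``f(t) = base_freq + speed_slope * speed(t)``, integrated to a phase so no
  phase slips occur at speed changes), each with a per-channel laminar
  gain/phase profile (theta phase reversal between pyramidal-layer and
  lacunosum-moleculare channels);
- gamma components whose amplitude envelope is modulated by a theta
  oscillator's phase (phase–amplitude coupling);
- animal tracking in a circular arena (or on a treadmill), with
  zone-dependent running speeds;
- optogenetic stimulation epochs that can gate oscillators on;
- spike trains of regular-spiking and interneuron units drawn from an
  inhomogeneous point process rate-modulated by theta phase (von Mises
  modulation, depth chosen to hit a target mean resultant length |R|), each
  with a stereotyped biphasic waveform template.

The same seed always yields bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0, i1

from .behavior import ArenaSpec, zone_index_of
from .units import Waveform, biphasic_template

__all__ = [
    "OscillatorSpec",
    "PACSpec",
    "UnitSpec",
    "SessionConfig",
    "SessionData",
    "generate_session",
    "generate_trajectory",
    "render_wideband",
    "default_laminar_profile",
    "kappa_for_resultant_length",
]

GATES = ("always", "stim_on", "zone_set", "immobility")
IMMOBILITY_SPEED = 5.0  # cm/s, below which the animal counts as immobile


@dataclass(frozen=True)
class OscillatorSpec:
    """A speed-dependent, gated sinusoidal LFP component.

    ``laminar_gain`` / ``laminar_phase`` (one entry per channel) shape the
    depth profile; by default all channels share gain 1 and a phase reversal
    is applied by :func:`default_laminar_profile` at session level.
    """

    name: str
    base_freq: float  # Hz at speed 0
    speed_slope: float = 0.0  # Hz per (cm/s)
    amplitude: float = 0.1  # mV
    gate: str = "always"
    zones: tuple[str, ...] = ()  # for gate == "zone_set"
    laminar_gain: tuple[float, ...] | None = None
    laminar_phase: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.base_freq <= 0:
            raise ValueError("base_freq must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.gate not in GATES:
            raise ValueError(f"unknown gate {self.gate!r}; choose from {GATES}")


@dataclass(frozen=True)
class PACSpec:
    """Gamma component amplitude-modulated by a theta oscillator's phase.

    The envelope is ``amplitude * (1 + depth * cos(phi - preferred)) / 2``,
    so depth 0 gives a constant envelope and depth 1 full modulation.
    """

    phase_source: str
    amp_center_freq: float  # Hz
    amp_bandwidth: float = 20.0  # Hz; 0 = pure-tone carrier
    modulation_depth: float = 0.8
    amplitude: float = 0.05  # mV
    preferred_phase: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.modulation_depth <= 1.0):
            raise ValueError("modulation_depth must lie in [0, 1]")


@dataclass(frozen=True)
class UnitSpec:
    """A simulated unit: rate, theta-phase coupling and waveform shape."""

    name: str
    unit_class: str = "RS"  # RS or IN
    mean_rate: float = 5.0  # spikes/s
    coupling_strength: float = 0.0  # target |R|
    preferred_phase: float = 0.0
    phase_source: str | None = None  # defaults to the first oscillator
    half_width: float = 0.36  # ms
    peak_trough_ratio: float = 12.3

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must lie in [0, 1]")


@dataclass
class SessionConfig:
    fs: float = 1000.0
    duration: float = 60.0  # s
    n_channels: int = 16
    channel_spacing: float = 50.0  # µm
    channel_strata: dict = field(default_factory=dict)
    oscillators: list[OscillatorSpec] = field(default_factory=list)
    pac: list[PACSpec] = field(default_factory=list)
    units: list[UnitSpec] = field(default_factory=list)
    noise_exponent: float = 1.0
    noise_amplitude: float = 0.02  # mV RMS
    arena: ArenaSpec | None = None
    trajectory_model: str = "treadmill"  # or "random_walk_in_arena"
    treadmill_speed: float = 10.0  # cm/s
    wall_bias: float = 0.0
    speed_by_zone: dict = field(default_factory=dict)  # cm/s targets per zone
    stim_epochs: list[tuple[float, float, float]] = field(default_factory=list)
    tracking_fs: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 1000:
            raise ValueError("fs must be at least 1000 Hz")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SessionData:
    """A generated session plus the ground truth it was built from."""

    lfp: np.ndarray  # channels x samples, mV
    fs: float
    tracking: pd.DataFrame  # t, x, y
    spikes: dict[str, np.ndarray]  # unit -> spike times (s)
    waveforms: dict[str, Waveform]
    stim_epochs: list[tuple[float, float, float]]
    config: SessionConfig
    ground_truth: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.fs


def default_laminar_profile(
    n_channels: int, reversal_channel: int | None = None
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Unit gains with a theta phase reversal below ``reversal_channel``
    (default: three-quarters of the way down the probe, mimicking the
    SP-to-SLM transition)."""
    if reversal_channel is None:
        reversal_channel = max(1, (3 * n_channels) // 4)
    gains = tuple(1.0 for _ in range(n_channels))
    phases = tuple(0.0 if c < reversal_channel else np.pi for c in range(n_channels))
    return gains, phases


def kappa_for_resultant_length(r: float) -> float:
    """Von Mises concentration giving mean resultant length ``r``.

    Inverts r = I1(kappa)/I0(kappa); r = 0 maps to 0 and r -> 1 saturates
    at a large finite concentration.
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError("r must lie in [0, 1]")
    if r < 1e-9:
        return 0.0
    if r > 0.998:
        r = 0.998
    return float(brentq(lambda k: i1(k) / i0(k) - r, 1e-9, 500.0))


def generate_trajectory(
    arena: ArenaSpec | None,
    duration: float,
    model: str,
    seed: int | np.random.Generator = 0,
    tracking_fs: float = 50.0,
    treadmill_speed: float = 10.0,
    wall_bias: float = 0.0,
    speed_by_zone: dict | None = None,
    speed_jitter: float = 0.5,
) -> pd.DataFrame:
    """Generate a ``t,x,y`` tracking table.

    ``treadmill`` moves at constant ``treadmill_speed`` along a straight
    line.  ``random_walk_in_arena`` is a reflected correlated random walk
    whose target speed depends on the current zone (``speed_by_zone``,
    default 7 cm/s in the Wall annulus and 25 cm/s in the inner zones —
    animals run faster when crossing the open centre) and whose radial
    drift toward the Wall annulus is controlled by ``wall_bias`` in [0, 1].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * tracking_fs))
    t = np.arange(n) / tracking_fs
    if model == "treadmill":
        x = treadmill_speed * t
        y = np.zeros(n)
        return pd.DataFrame({"t": t, "x": x, "y": y})
    if model != "random_walk_in_arena":
        raise ValueError(f"unknown trajectory model {model!r}")
    if arena is None:
        raise ValueError("random_walk_in_arena requires an arena")

    defaults = {name: 25.0 for name in arena.zone_names}
    defaults[arena.zone_names[-1]] = 7.0  # Wall
    if speed_by_zone:
        defaults.update(speed_by_zone)
    dt = 1.0 / tracking_fs
    wall_inner = arena.zone_boundaries[-2] if len(arena.zone_boundaries) > 1 else 0.0
    r_wall = 0.5 * (wall_inner + arena.radius)

    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([r_wall, 0.0])
    heading = rng.uniform(0, 2 * np.pi)
    v = defaults[arena.zone_names[-1]]
    # bout structure: the animal alternates between wall-hugging bouts and
    # excursions toward the centre; wall_bias is the probability that the
    # next bout targets the wall annulus
    goal_r = r_wall
    bout_left = rng.exponential(4.0)
    for i in range(n):
        x[i], y[i] = pos
        bout_left -= dt
        if bout_left <= 0:
            bout_left = rng.exponential(4.0)
            # excursions dwell anywhere in the inner region, not only at
            # the exact centre
            goal_r = (
                r_wall
                if rng.random() < wall_bias
                else rng.uniform(0.05, 0.95) * wall_inner
            )
        zone = arena.zone_names[int(zone_index_of(pos[0], pos[1], arena))]
        v_target = defaults[zone]
        v += (v_target - v) * (dt / 0.25) + speed_jitter * np.sqrt(dt) * rng.standard_normal()
        v = max(v, 0.5)
        heading += 0.8 * np.sqrt(dt) * rng.standard_normal()
        # steer toward the goal radius by rotating the heading, keeping the
        # step length (hence displacement speed) exactly v*dt
        r = np.hypot(*pos)
        if r > 1e-6:
            radial_dir = np.arctan2(pos[1], pos[0])
            bearing = radial_dir if r < goal_r else radial_dir + np.pi
            err = np.angle(np.exp(1j * (bearing - heading)))
            gain = 3.0 * min(1.0, abs(goal_r - r) / 4.0)
            heading += gain * err * dt
        pos = pos + v * dt * np.array([np.cos(heading), np.sin(heading)])
        r = np.hypot(*pos)
        if r > arena.radius:  # reflect at the wall
            pos *= (2 * arena.radius - r) / r
            heading += np.pi
    return pd.DataFrame({"t": t, "x": x, "y": y})


def _one_over_f_noise(n: int, fs: float, exponent: float, rms: float, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = np.std(x)
    return x * (rms / sd) if sd > 0 else x


def _smooth_gate(mask: np.ndarray, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    if not mask.any():
        return mask.astype(float)
    k = int(round(ramp_s * fs))
    if k < 2:
        return mask.astype(float)
    win = np.hanning(2 * k + 1)
    win /= win.sum()
    return np.convolve(mask.astype(float), win, mode="same")


def generate_session(config: SessionConfig) -> SessionData:
    """Build a full synthetic session from its configuration.

    The LFP on every channel is 1/f noise plus the sum of gated oscillators
    and phase-amplitude-coupled gamma components; spikes are drawn by
    thinning an inhomogeneous Poisson rate modulated by the (ground-truth)
    theta phase.  Identical configs (same seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    tracking = generate_trajectory(
        config.arena,
        config.duration,
        config.trajectory_model,
        seed=np.random.default_rng(rng.integers(2**31)),
        tracking_fs=config.tracking_fs,
        treadmill_speed=config.treadmill_speed,
        wall_bias=config.wall_bias,
        speed_by_zone=config.speed_by_zone,
    )
    tt = tracking["t"].to_numpy()
    dt_tr = 1.0 / config.tracking_fs
    vx = np.gradient(tracking["x"].to_numpy(), dt_tr)
    vy = np.gradient(tracking["y"].to_numpy(), dt_tr)
    speed_tr = np.hypot(vx, vy)
    speed = np.interp(t, tt, speed_tr)

    if config.arena is not None:
        xi = np.interp(t, tt, tracking["x"].to_numpy())
        yi = np.interp(t, tt, tracking["y"].to_numpy())
        zone_idx = zone_index_of(xi, yi, config.arena)
        zone_names = config.arena.zone_names
    else:
        zone_idx = None
        zone_names = ()

    stim_mask = np.zeros(n, dtype=bool)
    for start, end, _freq in config.stim_epochs:
        stim_mask[int(start * fs) : int(end * fs)] = True

    def gate_mask(osc: OscillatorSpec) -> np.ndarray:
        if osc.gate == "always":
            return np.ones(n, dtype=bool)
        if osc.gate == "stim_on":
            return stim_mask.copy()
        if osc.gate == "immobility":
            return speed < IMMOBILITY_SPEED
        if osc.gate == "zone_set":
            if zone_idx is None:
                raise ValueError(
                    f"oscillator {osc.name!r} gated on zones but the session has no arena"
                )
            bad = set(osc.zones) - set(zone_names)
            if bad:
                raise ValueError(f"unknown zones {bad} in oscillator {osc.name!r}")
            sel = np.array([name in osc.zones for name in zone_names])
            return sel[zone_idx]
        raise ValueError(f"invalid gate {osc.gate!r}")

    phases: dict[str, np.ndarray] = {}
    gates: dict[str, np.ndarray] = {}
    lfp = np.zeros((config.n_channels, n))
    for ci in range(config.n_channels):
        lfp[ci] = _one_over_f_noise(
            n, fs, config.noise_exponent, config.noise_amplitude, rng
        ) if config.noise_amplitude > 0 else 0.0

    gains_default, phase_off_default = default_laminar_profile(config.n_channels)
    for osc in config.oscillators:
        f_inst = osc.base_freq + osc.speed_slope * speed
        if np.any(f_inst <= 0):
            raise ValueError(f"oscillator {osc.name!r} reaches non-positive frequency")
        phase = 2 * np.pi * np.cumsum(f_inst) / fs
        phases[osc.name] = phase
        g = gate_mask(osc)
        gates[osc.name] = g
        gs = _smooth_gate(g, fs)
        gains = osc.laminar_gain or gains_default
        offs = osc.laminar_phase or phase_off_default
        if len(gains) != config.n_channels or len(offs) != config.n_channels:
            raise ValueError(f"laminar profile of {osc.name!r} does not match channel count")
        wave = gs * np.cos(phase)
        wave_pi = gs * np.cos(phase + np.pi)
        for ci in range(config.n_channels):
            if offs[ci] == 0.0:
                lfp[ci] += osc.amplitude * gains[ci] * wave
            elif offs[ci] == np.pi:
                lfp[ci] += osc.amplitude * gains[ci] * wave_pi
            else:
                lfp[ci] += osc.amplitude * gains[ci] * gs * np.cos(phase + offs[ci])

    for pac in config.pac:
        if pac.phase_source not in phases:
            raise ValueError(f"PAC references unknown oscillator {pac.phase_source!r}")
        phi = phases[pac.phase_source]
        gs = _smooth_gate(gates[pac.phase_source], fs)
        envelope = (
            pac.amplitude
            * (1.0 + pac.modulation_depth * np.cos(phi - pac.preferred_phase))
            / 2.0
        )
        if pac.amp_bandwidth > 0:
            # stochastic narrow-band carrier with a Gaussian spectral
            # profile peaked at the centre frequency (real gamma is a
            # band-limited noise process, not a pure tone)
            white = np.fft.rfft(rng.standard_normal(n))
            f_grid = np.fft.rfftfreq(n, 1.0 / fs)
            sigma_f = pac.amp_bandwidth / 4.0
            shape = np.exp(-((f_grid - pac.amp_center_freq) ** 2) / (2 * sigma_f**2))
            carrier = np.fft.irfft(white * shape, n)
            carrier *= np.sqrt(2.0) / np.std(carrier)
        else:
            carrier = np.cos(2 * np.pi * pac.amp_center_freq * t)
        lfp += (gs * envelope * carrier)[None, :]

    spikes: dict[str, np.ndarray] = {}
    waveforms: dict[str, Waveform] = {}
    for unit in config.units:
        source = unit.phase_source or (
            config.oscillators[0].name if config.oscillators else None
        )
        if unit.coupling_strength > 0 and source is None:
            raise ValueError(f"unit {unit.name!r} is coupled but no oscillator exists")
        if unit.coupling_strength > 0:
            kappa = kappa_for_resultant_length(unit.coupling_strength)
            rate = np.exp(kappa * np.cos(phases[source] - unit.preferred_phase))
            rate *= unit.mean_rate / i0(kappa)
        else:
            rate = np.full(n, unit.mean_rate)
        p = np.clip(rate / fs, 0.0, 1.0)
        mask = rng.random(n) < p
        spikes[unit.name] = t[mask]
        waveforms[unit.name] = biphasic_template(
            unit.half_width, unit.peak_trough_ratio
        )

    ground_truth = {
        "speed": speed,
        "phases": phases,
        "gates": gates,
        "stim_mask": stim_mask,
        "zone_index": zone_idx,
        "zone_names": zone_names,
    }
    return SessionData(
        lfp=lfp,
        fs=fs,
        tracking=tracking,
        spikes=spikes,
        waveforms=waveforms,
        stim_epochs=list(config.stim_epochs),
        config=config,
        ground_truth=ground_truth,
    )


def render_wideband(
    spike_times: np.ndarray,
    template: Waveform,
    duration: float,
    fs: float = 25_000.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Insert waveform templates into white noise at the given spike times,
    producing a wideband trace suitable for threshold spike detection."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    trace = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    w = np.asarray(template.samples, dtype=float)
    align = template.alignment
    for st in np.asarray(spike_times, dtype=float):
        i0_ = int(round(st * fs)) - align
        j0 = max(i0_, 0)
        j1 = min(i0_ + len(w), n)
        if j1 <= j0:
            continue
        trace[j0:j1] += w[j0 - i0_ : j1 - i0_]
    return trace
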