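"""Circular-arena geometry, zone assignment and behavioural metrics.

The arena is a disc divided into concentric annular zones (Center,
Intermediate, optionally an Extended Intermediate ring, and Wall).  Zone
membership is decided by radial distance; behavioural read-outs are
time-in-zone, zone-crossing counts and the assignment of LFP windows to the
zone/velocity the animal occupied while the window was recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .spectral import PowerSpectrum, compute_psd

__all__ = [
    "ArenaSpec",
    "ZoneTimeline",
    "assign_zone",
    "compute_speed",
    "zone_timeline",
    "zone_metrics",
    "segment_lfp_by_zone",
    "zone_psd",
]


@dataclass(frozen=True)
class ArenaSpec:
    """Circular arena with concentric zones.

    ``zone_boundaries`` are the outer radii of each zone in cm, strictly
    increasing with the last equal to the arena radius.  A point whose radial
    distance falls exactly on a boundary belongs to the inner zone of the
    pair (annuli are inner-inclusive at their outer edge).
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 25.0
    zone_boundaries: tuple[float, ...] = (8.0, 16.0, 25.0)
    zone_names: tuple[str, ...] = ("Center", "Intermediate", "Wall")

    def __post_init__(self) -> None:
        b = np.asarray(self.zone_boundaries, dtype=float)
        if b.ndim != 1 or len(b) != len(self.zone_names):
            raise ValueError("zone_boundaries and zone_names must have equal length")
        if np.any(np.diff(b) <= 0) or b[0] <= 0:
            raise ValueError("zone_boundaries must be positive and strictly increasing")
        if not np.isclose(b[-1], self.radius):
            raise ValueError("last zone boundary must equal the arena radius")

    @classmethod
    def extended(cls, radius: float = 25.0) -> "ArenaSpec":
        """Four-zone variant with an Extended Intermediate ring."""
        return cls(
            radius=radius,
            zone_boundaries=(0.32 * radius, 0.64 * radius, 0.8 * radius, radius),
            zone_names=("Center", "Intermediate", "ExtendedIntermediate", "Wall"),
        )


@dataclass
class ZoneTimeline:
    """Per-sample zone labels plus debounced crossing events."""

    t: np.ndarray
    zone_index: np.ndarray
    zone_names: tuple[str, ...]
    crossings: pd.DataFrame = field(repr=False)  # columns t, from_zone, to_zone

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.zone_names)[self.zone_index]


def _radii(x, y, arena: ArenaSpec) -> np.ndarray:
    return np.hypot(np.asarray(x) - arena.center[0], np.asarray(y) - arena.center[1])


def zone_index_of(x, y, arena: ArenaSpec) -> np.ndarray:
    """Vectorised zone index (0 = innermost).  Points beyond the arena radius
    are clipped into the outermost zone."""
    r = _radii(x, y, arena)
    idx = np.searchsorted(np.asarray(arena.zone_boundaries), r, side="left")
    return np.minimum(idx, len(arena.zone_names) - 1)


def assign_zone(x: float, y: float, arena: ArenaSpec) -> str:
    """Zone label of a single tracked point."""
    return arena.zone_names[int(zone_index_of(x, y, arena))]


def compute_speed(tracking: pd.DataFrame, smooth_s: float = 0.2) -> np.ndarray:
    """Instantaneous speed (cm/s) from a ``t,x,y`` tracking table.

    Positions are smoothed with a ``smooth_s`` moving average before a
    centred finite difference, suppressing tracker jitter.
    """
    t = tracking["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("tracking must contain at least two samples")
    dt = float(np.median(np.diff(t)))
    win = max(1, int(round(smooth_s / dt)))
    vx = np.gradient(tracking["x"].to_numpy(dtype=float), t)
    vy = np.gradient(tracking["y"].to_numpy(dtype=float), t)
    speed = np.hypot(vx, vy)
    if win == 1:
        return speed
    # moving average with edge windows normalized by their actual support,
    # so constant-speed trajectories stay exactly constant at the ends
    kernel = np.ones(win)
    num = np.convolve(speed, kernel, mode="same")
    den = np.convolve(np.ones_like(speed), kernel, mode="same")
    return num / den


def zone_timeline(
    tracking: pd.DataFrame, arena: ArenaSpec, debounce_s: float = 0.2
) -> ZoneTimeline:
    """Label every tracking sample with its zone and list crossing events.

    Labels are median-filtered over ``debounce_s`` so that brief boundary
    jitter does not register as crossings.  A (rare) jump across more than
    one boundary between consecutive samples is split into successive
    adjacent-zone events at the same timestamp.
    """
    t = tracking["t"].to_numpy(dtype=float)
    idx = zone_index_of(tracking["x"], tracking["y"], arena)
    if len(t) > 2:
        dt = float(np.median(np.diff(t)))
        k = max(1, int(round(debounce_s / dt)))
        if k % 2 == 0:
            k += 1
        idx = median_filter(idx, size=k, mode="nearest")
    events = []
    change = np.flatnonzero(np.diff(idx) != 0)
    for i in change:
        a, b = int(idx[i]), int(idx[i + 1])
        step = 1 if b > a else -1
        for z in range(a, b, step):
            events.append(
                (t[i + 1], arena.zone_names[z], arena.zone_names[z + step])
            )
    crossings = pd.DataFrame(events, columns=["t", "from_zone", "to_zone"])
    return ZoneTimeline(t=t, zone_index=idx, zone_names=arena.zone_names, crossings=crossings)


def zone_metrics(
    tracking: pd.DataFrame, arena: ArenaSpec, debounce_s: float = 0.2
) -> dict:
    """Time-in-zone, per-boundary crossing counts and crossing frequency.

    Returns a dict with keys ``time_in_zone`` (s per zone),
    ``crossing_counts`` (per ordered boundary pair), and
    ``crossing_frequency_per_min`` (per ordered pair).
    """
    tl = zone_timeline(tracking, arena, debounce_s)
    t = tl.t
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    duration_min = (t[-1] - t[0] + dt) / 60.0 if len(t) > 1 else np.nan
    time_in_zone = {
        name: float(np.sum(tl.zone_index == i) * dt)
        for i, name in enumerate(arena.zone_names)
    }
    counts: dict[tuple[str, str], int] = {}
    for _, row in tl.crossings.iterrows():
        key = (row["from_zone"], row["to_zone"])
        counts[key] = counts.get(key, 0) + 1
    freq = {k: v / duration_min for k, v in counts.items()}
    return {
        "time_in_zone": time_in_zone,
        "crossing_counts": counts,
        "crossing_frequency_per_min": freq,
        "timeline": tl,
    }


def segment_lfp_by_zone(
    lfp: np.ndarray,
    fs: float,
    tracking: pd.DataFrame,
    arena: ArenaSpec,
    window: float = 3.0,
    overlap: float = 2.5,
    min_walk: float = 2.0,
    walk_speed: float = 5.0,
    walking_filter: bool = False,
) -> dict[str, list[tuple[int, int]]]:
    """Assign overlapping LFP windows to arena zones.

    Windows of ``window`` s advancing by ``window - overlap`` s are labelled
    with the majority zone of the concurrent tracking samples.  With
    ``walking_filter`` enabled, a window is retained only when every one of
    its tracking samples lies inside a continuous walking bout
    (speed ≥ ``walk_speed`` cm/s) of at least ``min_walk`` s.

    Returns a mapping zone name → list of ``(start_sample, stop_sample)``
    index pairs into ``lfp``.
    """
    lfp = np.asarray(lfp)
    sig = lfp if lfp.ndim == 1 else lfp[0]
    t_track = tracking["t"].to_numpy(dtype=float)
    n_sec = len(sig) / fs
    if t_track[-1] < n_sec - window:
        raise ValueError("tracking does not cover the LFP duration (misaligned streams)")
    idx = zone_index_of(tracking["x"], tracking["y"], arena)
    speed = compute_speed(tracking)

    walk_ok = np.ones(len(t_track), dtype=bool)
    if walking_filter:
        walking = speed >= walk_speed
        walk_ok = np.zeros(len(t_track), dtype=bool)
        # mark samples belonging to bouts lasting >= min_walk
        i = 0
        while i < len(walking):
            if walking[i]:
                j = i
                while j < len(walking) and walking[j]:
                    j += 1
                if t_track[j - 1] - t_track[i] >= min_walk:
                    walk_ok[i:j] = True
                i = j
            else:
                i += 1

    step = window - overlap
    out: dict[str, list[tuple[int, int]]] = {name: [] for name in arena.zone_names}
    nper = int(round(window * fs))
    t0 = 0.0
    while t0 + window <= n_sec + 1e-9:
        start = int(round(t0 * fs))
        stop = start + nper
        if stop > len(sig):
            break
        mask = (t_track >= t0) & (t_track < t0 + window)
        if mask.any() and (not walking_filter or walk_ok[mask].all()):
            zone = arena.zone_names[int(np.bincount(idx[mask]).argmax())]
            out[zone].append((start, stop))
        t0 += step
    return out


def zone_psd(
    lfp: np.ndarray, fs: float, segments: list[tuple[int, int]], window: float = 3.0
) -> PowerSpectrum:
    """Average Hamming-tapered periodogram over a zone's LFP segments."""
    if not segments:
        raise ValueError("no segments for this zone")
    sig = np.asarray(lfp)
    if sig.ndim > 1:
        sig = sig[0]
    spectra = []
    for start, stop in segments:
        ps = compute_psd(sig[start:stop], fs, window_length=window, overlap=0.0)
        spectra.append(ps.power)
    return PowerSpectrum(
        freqs=ps.freqs,
        power=np.mean(spectra, axis=0),
        normalization="raw",
        window_length=window,
        overlap=0.0,
    )
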