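"""Offline replay of the real-time theta2 band-power trigger.

The controller mirrors a closed-loop optogenetic rig: a 30-s baseline of
LFP is recorded, its mean 6–8 Hz band power computed, and the incoming
signal is then processed in 1/8-s chunks.  The laser output is activated
for a chunk when (a) the chunk's theta2 band power exceeds the baseline
mean times a threshold (2.5) and (b) the animal's speed over the chunk is
above 5 cm/s (movement mode) or below 5 cm/s (immobility mode).  All
comparisons are strict, so the switching points sit exactly at the
threshold ratio and at 5 cm/s.

A 0.125-s chunk has an intrinsic 8-Hz frequency resolution; the chunk PSD
is therefore zero-padded (default to 1 s) so the 6–8 Hz band power is read
from an interpolated spectrum.  Baseline and chunks use the identical
estimator, making the power ratio of a scaled copy of a chunk exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ControllerConfig",
    "ChunkRecord",
    "TriggerLog",
    "chunk_band_power",
    "compute_baseline",
    "step",
    "replay",
    "validate",
]


@dataclass(frozen=True)
class ControllerConfig:
    baseline_duration: float = 30.0  # s
    band: tuple[float, float] = (6.0, 8.0)  # Hz
    chunk_length: float = 0.125  # s
    threshold: float = 2.5  # power ratio
    speed_criterion: float = 5.0  # cm/s
    mode: str = "movement"  # or "immobility"
    pad_to: float = 1.0  # s, zero-padding for the chunk PSD

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.chunk_length <= 0:
            raise ValueError("threshold and chunk_length must be positive")
        if self.mode not in ("movement", "immobility"):
            raise ValueError("mode must be 'movement' or 'immobility'")


@dataclass
class ChunkRecord:
    t_start: float
    band_power: float
    power_ratio: float
    speed: float
    power_gate: bool
    speed_gate: bool
    laser_on: bool


@dataclass
class TriggerLog:
    """Per-chunk decisions of the controller."""

    records: list[ChunkRecord] = field(default_factory=list)
    config: ControllerConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def laser_on(self) -> np.ndarray:
        return np.array([r.laser_on for r in self.records], dtype=bool)


def chunk_band_power(
    chunk: np.ndarray, fs: float, band: tuple[float, float], pad_to: float = 1.0
) -> float:
    """Rectangular-window periodogram band power of one chunk.

    The chunk is zero-padded to ``pad_to`` seconds and the band power is the
    sum of periodogram bins whose frequency lies in [lo, hi] inclusive.
    """
    chunk = np.asarray(chunk, dtype=float)
    nfft = max(int(round(pad_to * fs)), len(chunk))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    psd = np.abs(np.fft.rfft(chunk, nfft)) ** 2 / (len(chunk) * fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[mask].sum())


def compute_baseline(
    signal: np.ndarray, fs: float, config: ControllerConfig = ControllerConfig()
) -> float:
    """Mean theta2 band power over the baseline period's chunks.

    Uses the same chunk-wise estimator as :func:`step`, so a stationary
    signal yields per-chunk ratios centred on 1.
    """
    signal = np.asarray(signal, dtype=float)
    n_needed = int(round(config.baseline_duration * fs))
    if signal.size < n_needed:
        raise ValueError(
            f"baseline needs {config.baseline_duration} s, got {signal.size / fs:.2f} s"
        )
    nper = int(round(config.chunk_length * fs))
    powers = [
        chunk_band_power(signal[i : i + nper], fs, config.band, config.pad_to)
        for i in range(0, n_needed - nper + 1, nper)
    ]
    baseline = float(np.mean(powers))
    if baseline <= 0:
        raise ValueError("baseline band power is zero; invalid baseline signal")
    return baseline


def step(
    chunk: np.ndarray,
    speed: float,
    baseline_power: float,
    fs: float,
    config: ControllerConfig = ControllerConfig(),
    t_start: float = 0.0,
) -> ChunkRecord:
    """One controller decision for a single chunk.

    ``power_gate`` is True when band power strictly exceeds
    ``threshold * baseline_power``; ``speed_gate`` when speed is strictly
    above (movement) or strictly below (immobility) the 5 cm/s criterion.
    The laser fires only when both gates are open, and only for this chunk.
    """
    chunk = np.asarray(chunk, dtype=float)
    nper = int(round(config.chunk_length * fs))
    if len(chunk) != nper:
        raise ValueError(f"chunk length {len(chunk)} != expected {nper} samples")
    bp = chunk_band_power(chunk, fs, config.band, config.pad_to)
    ratio = bp / baseline_power
    power_gate = bp > config.threshold * baseline_power
    if config.mode == "movement":
        speed_gate = speed > config.speed_criterion
    else:
        speed_gate = speed < config.speed_criterion
    return ChunkRecord(
        t_start=t_start,
        band_power=bp,
        power_ratio=ratio,
        speed=float(speed),
        power_gate=bool(power_gate),
        speed_gate=bool(speed_gate),
        laser_on=bool(power_gate and speed_gate),
    )


def replay(session, config: ControllerConfig = ControllerConfig(), channel: int = 0) -> TriggerLog:
    """Run the controller over a recorded session.

    The first ``baseline_duration`` seconds provide the baseline; the
    remainder is processed chunk by chunk.  Chunk speed is the tracked
    centroid displacement across the chunk divided by the chunk duration.
    Replay is fully deterministic.
    """
    lfp = np.atleast_2d(session.lfp)[channel]
    fs = session.fs
    if len(lfp) / fs <= config.baseline_duration:
        raise ValueError("session shorter than the baseline period")
    baseline = compute_baseline(lfp, fs, config)
    t_track = session.tracking["t"].to_numpy(dtype=float)
    x = session.tracking["x"].to_numpy(dtype=float)
    y = session.tracking["y"].to_numpy(dtype=float)

    nper = int(round(config.chunk_length * fs))
    start = int(round(config.baseline_duration * fs))
    log = TriggerLog(config=config)
    for i in range(start, len(lfp) - nper + 1, nper):
        t0 = i / fs
        t1 = t0 + config.chunk_length
        dx = np.interp(t1, t_track, x) - np.interp(t0, t_track, x)
        dy = np.interp(t1, t_track, y) - np.interp(t0, t_track, y)
        speed = float(np.hypot(dx, dy) / config.chunk_length)
        log.records.append(
            step(lfp[i : i + nper], speed, baseline, fs, config, t_start=t0)
        )
    return log


def validate(
    log: TriggerLog, ground_truth_intervals: list[tuple[float, float]]
) -> tuple[float, float, float]:
    """Chunk-level confusion of the trigger log against known theta2-on
    intervals.

    Returns ``(sensitivity, specificity, median_latency_chunks)`` where the
    latency of an interval is the number of chunks from its onset to the
    first trigger inside it (NaN-free median over detected intervals; NaN
    when nothing was detected).
    """
    if not log.records:
        raise ValueError("empty trigger log")
    mids = np.array([r.t_start for r in log.records]) + log.config.chunk_length / 2
    truth = np.zeros(len(mids), dtype=bool)
    for a, b in ground_truth_intervals:
        truth |= (mids >= a) & (mids < b)
    laser = log.laser_on
    tp = int(np.sum(laser & truth))
    fn = int(np.sum(~laser & truth))
    fp = int(np.sum(laser & ~truth))
    tn = int(np.sum(~laser & ~truth))
    sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    latencies = []
    starts = np.array([r.t_start for r in log.records])
    for a, b in ground_truth_intervals:
        inside = np.flatnonzero((mids >= a) & (mids < b) & laser)
        if inside.size:
            latencies.append((starts[inside[0]] - a) / log.config.chunk_length)
    median_latency = float(np.median(latencies)) if latencies else float("nan")
    return float(sensitivity), float(specificity), median_latency
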