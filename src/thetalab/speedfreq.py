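"""Speed–frequency analysis: time-binned running speeds, speed-binned
relative power, and per-frequency power–speed correlation.

Following the approach of Ahmed & Mehta, a session is divided into 200-ms
time bins, each labelled with its mean running speed (and arena zone); the
speed distribution is further divided into 30 speed bins, and for every
speed bin the relative LFP power at each frequency is computed from the
discrete Fourier transform of the member time bins.  A per-frequency
weighted regression of relative power on speed then classifies frequencies
into significantly positively / negatively / non-correlated with speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .behavior import ArenaSpec, compute_speed, zone_index_of

__all__ = [
    "SpeedFrequencyMap",
    "bin_speeds",
    "speed_frequency_map",
    "power_speed_correlation",
    "ridge_frequencies",
]


@dataclass
class SpeedFrequencyMap:
    speed_bin_centers: np.ndarray  # cm/s
    freqs: np.ndarray  # Hz
    rel_power: np.ndarray  # speed-bins x freqs, each non-empty row sums to 1
    counts: np.ndarray  # time bins per speed bin

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


def bin_speeds(
    tracking: pd.DataFrame,
    bin_length: float = 0.2,
    arena: ArenaSpec | None = None,
) -> pd.DataFrame:
    """Mean running speed per contiguous ``bin_length`` (s) time bin.

    Returns a table with columns ``t_start``, ``speed`` and, when an arena
    is supplied, the majority ``zone`` of the bin.
    """
    if len(tracking) == 0:
        raise ValueError("empty tracking")
    t = tracking["t"].to_numpy(dtype=float)
    speed = compute_speed(tracking)
    duration = t[-1] - t[0] + float(np.median(np.diff(t)))
    n_bins = int(round(duration / bin_length))
    if n_bins == 0:
        raise ValueError("tracking shorter than one time bin")
    which = np.minimum(((t - t[0]) / bin_length).astype(int), n_bins - 1)
    rows = []
    if arena is not None:
        zidx = zone_index_of(tracking["x"], tracking["y"], arena)
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        row = {"t_start": t[0] + b * bin_length, "speed": float(np.mean(speed[mask]))}
        if arena is not None:
            row["zone"] = arena.zone_names[int(np.bincount(zidx[mask]).argmax())]
        rows.append(row)
    return pd.DataFrame(rows)


def speed_frequency_map(
    lfp: np.ndarray,
    fs: float,
    speed_bins: pd.DataFrame,
    n_speed_bins: int = 30,
    band: tuple[float, float] = (1.0, 20.0),
    bin_length: float = 0.2,
    pad_factor: int = 10,
    freq_smoothing: float = 1.0,
) -> SpeedFrequencyMap:
    """Relative power per (speed bin, frequency).

    The LFP stretches of all time bins falling into a speed bin are
    concatenated (in time order) and a single DFT power spectrum is taken —
    running speed is strongly autocorrelated, so the members of a speed bin
    are mostly contiguous and the concatenated record stays nearly coherent,
    giving a far sharper frequency estimate than a 200-ms window could.
    Spectra are interpolated onto a common ``1/(pad_factor * bin_length)``
    grid, smoothed over ``freq_smoothing`` Hz (a Hann kernel; 0 disables)
    and normalized so every non-empty row sums to 1 over ``band``.  Empty
    speed bins are flagged by ``counts == 0`` and excluded downstream.
    """
    sig = np.asarray(lfp, dtype=float)
    if sig.ndim > 1:
        sig = sig[0]
    nper = int(round(bin_length * fs))
    df = 1.0 / (pad_factor * bin_length)
    freqs = np.arange(band[0], band[1] + df / 2, df)

    speeds = speed_bins["speed"].to_numpy(dtype=float)
    edges = np.linspace(speeds.min(), speeds.max() + 1e-9, n_speed_bins + 1)
    which = np.clip(np.digitize(speeds, edges) - 1, 0, n_speed_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    members: list[list[np.ndarray]] = [[] for _ in range(n_speed_bins)]
    counts = np.zeros(n_speed_bins, dtype=int)
    for (_, row), b in zip(speed_bins.iterrows(), which):
        start = int(round(row["t_start"] * fs))
        seg = sig[start : start + nper]
        if len(seg) < nper:
            continue
        members[b].append(seg)
        counts[b] += 1

    rel = np.zeros((n_speed_bins, freqs.size))
    for b in range(n_speed_bins):
        if counts[b] == 0:
            continue
        rec = np.concatenate(members[b])
        rec = rec - rec.mean()
        nfft = max(len(rec), int(round(fs / df)))
        spec = np.abs(np.fft.rfft(rec, nfft)) ** 2
        grid = np.fft.rfftfreq(nfft, 1.0 / fs)
        row_p = np.interp(freqs, grid, spec)
        if freq_smoothing > 0:
            # Hann taper endpoints are zero, so use 2m+1 points for an
            # effective full width of ~freq_smoothing
            k = 2 * int(round(freq_smoothing / df)) + 1
            if k >= 5:
                kern = np.hanning(k)
                kern /= kern.sum()
                row_p = np.convolve(row_p, kern, mode="same")
        total = row_p.sum()
        if total > 0:
            rel[b] = row_p / total
    return SpeedFrequencyMap(
        speed_bin_centers=centers, freqs=freqs, rel_power=rel, counts=counts
    )


def ridge_frequencies(sfmap: SpeedFrequencyMap) -> np.ndarray:
    """Per speed bin, the frequency of maximal relative power (parabolic
    sub-bin refinement); NaN for empty bins."""
    out = np.full(len(sfmap.speed_bin_centers), np.nan)
    df = sfmap.freqs[1] - sfmap.freqs[0]
    for b in range(len(out)):
        if sfmap.counts[b] == 0:
            continue
        row = sfmap.rel_power[b]
        i = int(np.argmax(row))
        f = sfmap.freqs[i]
        if 0 < i < len(row) - 1:
            denom = row[i - 1] - 2 * row[i] + row[i + 1]
            if denom < 0:
                f += 0.5 * (row[i - 1] - row[i + 1]) / denom * df
        out[b] = f
    return out


def power_speed_correlation(
    sfmap: SpeedFrequencyMap, alpha: float = 0.001, min_bins: int = 5
) -> pd.DataFrame:
    """Per-frequency weighted regression of relative power on speed.

    For every frequency, relative power across non-empty speed bins is
    regressed on the speed-bin centers (weighted least squares, weights =
    time-bin counts).  Frequencies with regression p < ``alpha`` are
    classified ``positive`` or ``negative`` by slope sign, otherwise
    ``none``.  Returns a table with columns ``freq, slope, r, p, cls``.
    """
    keep = sfmap.nonempty
    if keep.sum() < min_bins:
        raise ValueError(f"need at least {min_bins} non-empty speed bins")
    x = sfmap.speed_bin_centers[keep]
    w = sfmap.counts[keep].astype(float)
    X = sm.add_constant(x)
    rows = []
    for j, f in enumerate(sfmap.freqs):
        y = sfmap.rel_power[keep, j]
        if np.allclose(y, y[0]):
            rows.append({"freq": f, "slope": 0.0, "r": 0.0, "p": 1.0, "cls": "none"})
            continue
        fit = sm.WLS(y, X, weights=w).fit()
        slope = float(fit.params[1])
        p = float(fit.pvalues[1])
        r = float(np.sign(slope) * np.sqrt(max(fit.rsquared, 0.0)))
        cls = "none"
        if p < alpha:
            cls = "positive" if slope > 0 else "negative"
        rows.append({"freq": f, "slope": slope, "r": r, "p": p, "cls": cls})
    return pd.DataFrame(rows)
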