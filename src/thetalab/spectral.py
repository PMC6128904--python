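"""Power spectra, spectrograms, band powers and theta-peak detection.

Spectral estimates follow the conventions used for hippocampal LFP work:
Welch averaging over 3-s Hamming-tapered segments with 2.5-s overlap, and
normalization of a power spectrum by the total 0–14 Hz power of a
pre-stimulation baseline so that spectra from different recordings can be
merged on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "PowerSpectrum",
    "Spectrogram",
    "BandDefinition",
    "compute_psd",
    "normalize_psd",
    "band_power",
    "detect_theta_peaks",
    "spectrogram",
]


@dataclass
class PowerSpectrum:
    """One-sided power spectral density with normalization provenance.

    ``power`` is in mV²/Hz when ``normalization == "raw"`` and dimensionless
    (per Hz) after baseline normalization.
    """

    freqs: np.ndarray
    power: np.ndarray
    normalization: str = "raw"
    window_length: float = 3.0
    overlap: float = 2.5

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class Spectrogram:
    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # freqs x times
    window_length: float
    step: float


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError("band requires 0 < lo < hi")


THETA2_10CMS = BandDefinition("theta2", 6.0, 7.5)
THETA1_10CMS = BandDefinition("theta1", 7.5, 9.0)
THETA2_25CMS = BandDefinition("theta2", 6.0, 8.0)
THETA1_25CMS = BandDefinition("theta1", 8.0, 10.0)


def compute_psd(
    signal: np.ndarray,
    fs: float,
    window_length: float = 3.0,
    overlap: float = 2.5,
) -> PowerSpectrum:
    """Welch PSD over Hamming-tapered overlapping segments.

    Frequency resolution is ``1 / window_length``.  Segments are detrended
    by their mean only.  ``overlap = 0`` gives non-overlapping segments; a
    single segment reduces to a plain tapered periodogram.
    """
    signal = np.asarray(signal, dtype=float)
    nperseg = int(round(window_length * fs))
    if signal.size < nperseg:
        raise ValueError(
            f"signal ({signal.size} samples) shorter than one window ({nperseg})"
        )
    noverlap = int(round(overlap * fs))
    if noverlap >= nperseg:
        raise ValueError("overlap must be shorter than the window")
    freqs, power = sps.welch(
        signal,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        average="mean",
    )
    return PowerSpectrum(
        freqs=freqs,
        power=power,
        normalization="raw",
        window_length=window_length,
        overlap=overlap,
    )


def normalize_psd(psd: PowerSpectrum, baseline_psd: PowerSpectrum) -> PowerSpectrum:
    """Divide a spectrum by the baseline's integrated 0–14 Hz power.

    Normalizing a baseline by itself therefore integrates to exactly 1 over
    0–14 Hz, which is the property the merge-across-recordings convention
    relies on.
    """
    if psd.freqs.shape != baseline_psd.freqs.shape or not np.allclose(
        psd.freqs, baseline_psd.freqs
    ):
        raise ValueError("spectra are on different frequency grids")
    denom = band_power(baseline_psd, BandDefinition("norm", 1e-12, 14.0))
    if denom <= 0:
        raise ValueError("baseline has zero power in 0-14 Hz; cannot normalize")
    return PowerSpectrum(
        freqs=psd.freqs,
        power=psd.power / denom,
        normalization="baseline_total_0_14",
        window_length=psd.window_length,
        overlap=psd.overlap,
    )


def band_power(psd: PowerSpectrum, band: BandDefinition) -> float:
    """Trapezoidal integral of power over [lo, hi].

    Band edges that fall between grid points are linearly interpolated, so
    band powers are exactly additive over a split of the band.
    """
    f, p = psd.freqs, psd.power
    if band.lo < f[0] - 1e-9 or band.hi > f[-1] + 1e-9:
        raise ValueError(
            f"band [{band.lo}, {band.hi}] outside spectrum range [{f[0]}, {f[-1]}]"
        )
    inner = (f > band.lo) & (f < band.hi)
    fg = np.concatenate(([band.lo], f[inner], [band.hi]))
    pg = np.concatenate(
        ([np.interp(band.lo, f, p)], p[inner], [np.interp(band.hi, f, p)])
    )
    return float(np.trapezoid(pg, fg))


def _one_over_f_trend(psd: PowerSpectrum, fit_lo=2.0, fit_hi=20.0, exclude=(4.0, 12.0)):
    """Fit log-power = a + b log-f over the fit range excluding the theta
    window; returns trend power evaluated on the full grid."""
    f, p = psd.freqs, psd.power
    mask = (f >= fit_lo) & (f <= fit_hi) & ~((f > exclude[0]) & (f < exclude[1]))
    mask &= p > 0
    if mask.sum() < 3:
        return np.full_like(p, np.median(p[p > 0]) if np.any(p > 0) else 0.0)
    lf, lp = np.log10(f[mask]), np.log10(p[mask])
    b, a = np.polyfit(lf, lp, 1)
    with np.errstate(divide="ignore"):
        trend = 10 ** (a + b * np.log10(np.maximum(f, f[f > 0][0])))
    return trend


def detect_theta_peaks(
    psd: PowerSpectrum,
    search_lo: float = 4.0,
    search_hi: float = 12.0,
    prominence_factor: float = 1.5,
    max_peaks: int = 2,
) -> list[tuple[float, float]]:
    """Locate theta peaks above the local 1/f trend.

    A local maximum within ``[search_lo, search_hi]`` counts as a peak when
    its power exceeds ``prominence_factor`` times the 1/f background fitted
    over 2–20 Hz (theta window excluded).  The ``max_peaks`` largest peaks
    are returned sorted by frequency; peak frequencies are refined by
    parabolic interpolation of log-power around the maximum bin.  A flat or
    peak-free spectrum yields an empty list.
    """
    f, p = psd.freqs, psd.power
    trend = _one_over_f_trend(psd)
    sel = np.flatnonzero((f >= search_lo) & (f <= search_hi))
    if sel.size < 3:
        return []
    idx_local, _ = sps.find_peaks(p[sel])
    peaks = []
    for i in idx_local:
        gi = sel[i]
        if p[gi] > prominence_factor * trend[gi]:
            # parabolic refinement on log power
            freq = f[gi]
            if 0 < gi < len(f) - 1 and p[gi - 1] > 0 and p[gi + 1] > 0:
                y0, y1, y2 = np.log(p[gi - 1]), np.log(p[gi]), np.log(p[gi + 1])
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    freq = f[gi] + 0.5 * (y0 - y2) / denom * psd.df
            peaks.append((float(freq), float(p[gi])))
    peaks.sort(key=lambda q: q[1], reverse=True)
    peaks = peaks[:max_peaks]
    peaks.sort(key=lambda q: q[0])
    return peaks


def spectrogram(
    signal: np.ndarray, fs: float, window_length: float = 3.0, step: float = 0.5
) -> Spectrogram:
    """Time–frequency power: each column is the single-segment Hamming
    periodogram of the corresponding window (no averaging)."""
    signal = np.asarray(signal, dtype=float)
    nperseg = int(round(window_length * fs))
    if signal.size < nperseg:
        raise ValueError("signal shorter than one window")
    nstep = int(round(step * fs))
    freqs, times, power = sps.spectrogram(
        signal,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg - nstep,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    return Spectrogram(
        times=times, freqs=freqs, power=power, window_length=window_length, step=step
    )
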