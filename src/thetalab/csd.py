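"""One-dimensional current-source-density estimation on laminar probes.

The CSD is estimated by the standard second spatial difference of the
potential across equally spaced contacts,

    csd_i = -(V_{i-1} - 2 V_i + V_{i+1}) / h^2 ,

with the sign convention that positive values are current sources.  The two
edge channels are dropped (optionally retained via Vaknin padding, which
duplicates the edge potentials before differencing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cfc import bandpass

__all__ = ["CSDMap", "compute_csd", "band_csd_amplitude"]


@dataclass
class CSDMap:
    csd: np.ndarray  # retained-channels x samples; positive = source
    depths: np.ndarray  # µm of retained channels
    spacing: float  # µm


def compute_csd(
    laminar_lfp: np.ndarray,
    spacing: float,
    vaknin: bool = False,
    smooth: bool = False,
) -> CSDMap:
    """Second-spatial-difference CSD across channels.

    ``laminar_lfp`` is channels x samples with channels ordered by depth at
    uniform ``spacing`` (µm).  ``vaknin`` pads by duplicating the edge
    channels so no channel is lost; ``smooth`` applies a (1,2,1)/4 spatial
    Hamming smoothing to the potentials first.
    """
    v = np.atleast_2d(np.asarray(laminar_lfp, dtype=float))
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if v.shape[0] < 3:
        raise ValueError("CSD requires at least 3 channels")
    if smooth:
        v = np.vstack([v[:1], v, v[-1:]])
        v = (v[:-2] + 2 * v[1:-1] + v[2:]) / 4.0
    depths = np.arange(v.shape[0]) * spacing
    if vaknin:
        v = np.vstack([v[:1], v, v[-1:]])
        kept = depths
    else:
        kept = depths[1:-1]
    csd = -(v[:-2] - 2 * v[1:-1] + v[2:]) / spacing**2
    return CSDMap(csd=csd, depths=kept, spacing=spacing)


def band_csd_amplitude(
    csdmap: CSDMap, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Per-channel RMS of the band-filtered CSD (e.g. theta-band CSD
    amplitude for locating the dominant laminar source)."""
    out = np.empty(csdmap.csd.shape[0])
    for i, row in enumerate(csdmap.csd):
        if np.allclose(row, 0):
            out[i] = 0.0
        else:
            out[i] = float(np.sqrt(np.mean(bandpass(row, fs, *band) ** 2)))
    return out
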