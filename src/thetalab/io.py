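"""Session container I/O: HDF5 round-trip plus CSV exports.

The HDF5 layout mirrors the in-memory :class:`~thetalab.synth.SessionData`:
datasets ``lfp`` (channels x samples), ``tracking`` (t,x,y columns),
``spikes/<unit>`` (times, s) and ``waveforms/<unit>``; the generating
configuration is stored as a JSON string attribute so a file is
self-describing.  Ground-truth arrays are not persisted — a re-loaded
session carries only what a real recording would.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import ArenaSpec
from .synth import (
    OscillatorSpec,
    PACSpec,
    SessionConfig,
    SessionData,
    UnitSpec,
)
from .units import Waveform

__all__ = [
    "write_session",
    "read_session",
    "config_to_dict",
    "config_from_dict",
    "export_tracking_csv",
    "import_tracking_csv",
    "export_stim_epochs_csv",
    "import_stim_epochs_csv",
]


def config_to_dict(config: SessionConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.arena is not None:
        d["arena"] = dataclasses.asdict(config.arena)
    return d


def config_from_dict(d: dict) -> SessionConfig:
    d = dict(d)
    if d.get("arena"):
        a = d["arena"]
        d["arena"] = ArenaSpec(
            center=tuple(a["center"]),
            radius=a["radius"],
            zone_boundaries=tuple(a["zone_boundaries"]),
            zone_names=tuple(a["zone_names"]),
        )
    d["oscillators"] = [
        OscillatorSpec(**{**o, "zones": tuple(o.get("zones", ())),
                          "laminar_gain": tuple(o["laminar_gain"]) if o.get("laminar_gain") else None,
                          "laminar_phase": tuple(o["laminar_phase"]) if o.get("laminar_phase") else None})
        for o in d.get("oscillators", [])
    ]
    d["pac"] = [PACSpec(**p) for p in d.get("pac", [])]
    d["units"] = [UnitSpec(**u) for u in d.get("units", [])]
    d["stim_epochs"] = [tuple(e) for e in d.get("stim_epochs", [])]
    return SessionConfig(**d)


def write_session(session: SessionData, path: str | Path) -> None:
    """Write a session to an HDF5 container (lossless for all arrays)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp)
        f.create_dataset("tracking", data=session.tracking[["t", "x", "y"]].to_numpy())
        f.create_dataset(
            "stim_epochs",
            data=np.asarray(session.stim_epochs, dtype=float).reshape(-1, 3),
        )
        sp = f.create_group("spikes")
        wf = f.create_group("waveforms")
        for name, times in session.spikes.items():
            sp.create_dataset(name, data=np.asarray(times, dtype=float))
            w = session.waveforms[name]
            d = wf.create_dataset(name, data=w.samples)
            d.attrs["fs"] = w.fs
            d.attrs["alignment"] = w.alignment
        f.attrs["fs"] = session.fs
        f.attrs["config"] = json.dumps(config_to_dict(session.config))


def read_session(path: str | Path) -> SessionData:
    """Read a session container; raises naming any missing dataset."""
    with h5py.File(path, "r") as f:
        for required in ("lfp", "tracking"):
            if required not in f:
                raise ValueError(f"container is missing the {required!r} dataset")
        lfp = f["lfp"][()]
        tr = f["tracking"][()]
        tracking = pd.DataFrame(tr, columns=["t", "x", "y"])
        stim = [tuple(row) for row in f["stim_epochs"][()]] if "stim_epochs" in f else []
        spikes, waveforms = {}, {}
        if "spikes" in f:
            for name in f["spikes"]:
                spikes[name] = f["spikes"][name][()]
                d = f["waveforms"][name]
                waveforms[name] = Waveform(
                    samples=d[()], fs=float(d.attrs["fs"]), alignment=int(d.attrs["alignment"])
                )
        config = config_from_dict(json.loads(f.attrs["config"]))
        fs = float(f.attrs["fs"])
    return SessionData(
        lfp=lfp,
        fs=fs,
        tracking=tracking,
        spikes=spikes,
        waveforms=waveforms,
        stim_epochs=stim,
        config=config,
    )


def export_tracking_csv(session: SessionData, path: str | Path) -> None:
    session.tracking[["t", "x", "y"]].to_csv(path, index=False)


def import_tracking_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"tracking CSV missing columns {sorted(missing)}")
    return df[["t", "x", "y"]]


def export_stim_epochs_csv(session: SessionData, path: str | Path) -> None:
    pd.DataFrame(session.stim_epochs, columns=["start", "end", "freq"]).to_csv(
        path, index=False
    )


def import_stim_epochs_csv(path: str | Path) -> list[tuple[float, float, float]]:
    df = pd.read_csv(path)
    return [tuple(row) for row in df[["start", "end", "freq"]].to_numpy()]
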