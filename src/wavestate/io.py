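"""HDF5 container I/O for recordings and ground truth.

Layout
------
``/vsd/data`` (frames x channels, float32), ``/vsd/rate``, ``/vsd/t0``,
``/vsd/positions`` (n x 2, mm), ``/vsd/spacing``, ``/vsd/ring_channels``;
``/laminar/lfp`` (depths x samples, mV), ``/laminar/rate``,
``/laminar/pitch``, ``/laminar/mode``, ``/laminar/true_csd``,
``/laminar/mua/<ch>`` (timestamps, s);
``/ecog/signal`` (µV), ``/ecog/rate``, ``/ecog/band``;
``/truth/*`` mirroring the ground-truth record.  A JSON sidecar
(``<file>.json``) stores the generation parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import ArrayGeometry
from .synth import VSDRecording, GroundTruth, LaminarRecording, ECoGTrace

__all__ = ["SchemaError", "RecordingIOError", "save_recording",
           "read_recording", "read_truth", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A required dataset or attribute is missing from the container."""


class RecordingIOError(IOError):
    """The container could not be read (corrupt or truncated file)."""


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def save_recording(path, rec, truth: GroundTruth | None = None,
                   params: dict | None = None) -> None:
    """Write a recording (and optional ground truth) to an HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if isinstance(rec, VSDRecording):
            g = f.create_group("vsd")
            g.create_dataset("data", data=np.asarray(rec.data, np.float32))
            g["rate"] = rec.rate
            g["t0"] = rec.t0
            g["positions"] = rec.geometry.positions
            g["spacing"] = rec.geometry.spacing
            g["ring_channels"] = np.asarray(rec.geometry.ring_channels)
        elif isinstance(rec, LaminarRecording):
            g = f.create_group("laminar")
            g["lfp"] = rec.lfp
            g["rate"] = rec.rate
            g["pitch"] = rec.pitch
            g.attrs["mode"] = rec.mode
            g["true_csd"] = rec.true_csd
            g["up_times"] = rec.up_times
            if rec.sg_fraction is not None:
                g.attrs["sg_fraction"] = rec.sg_fraction
            mg = g.create_group("mua")
            for ch, times in enumerate(rec.mua_times):
                mg[str(ch)] = np.asarray(times, dtype=float)
        elif isinstance(rec, ECoGTrace):
            g = f.create_group("ecog")
            g["signal"] = rec.signal
            g["rate"] = rec.rate
            g["band"] = np.asarray(rec.band, dtype=float)
            g["seg_len"] = rec.seg_len
            g["true_state_labels"] = np.asarray(
                [s.encode() for s in rec.true_state_labels])
            if rec.episodes:
                g["episode_state"] = np.asarray(
                    [s.encode() for s, _, _ in rec.episodes])
                g["episode_start"] = np.asarray(
                    [t for _, t, _ in rec.episodes], dtype=float)
                g["episode_dur"] = np.asarray(
                    [d for _, _, d in rec.episodes], dtype=float)
        else:
            raise TypeError(f"unsupported recording type {type(rec)!r}")
        if truth is not None:
            tg = f.create_group("truth")
            tg["state_labels"] = np.asarray(
                [s.encode() for s in truth.state_labels])
            tg["wave_times"] = truth.wave_times
            tg["wave_speeds"] = truth.wave_speeds
            tg["wave_directions"] = truth.wave_directions
            if truth.laminar_sg_fraction is not None:
                tg.attrs["laminar_sg_fraction"] = truth.laminar_sg_fraction
    if params is not None:
        _sidecar(path).write_text(
            json.dumps({"schema_version": SCHEMA_VERSION, "params": params},
                       indent=2, default=float))


def _require(f, name):
    if name not in f:
        raise SchemaError(f"missing dataset {name!r}")
    return f[name]


def read_recording(path, kind: str):
    """Read a recording back from a container.

    `kind` is ``"vsd"``, ``"laminar"`` or ``"ecog"``.  Missing datasets
    raise :class:`SchemaError` naming the absent path; unreadable files
    raise :class:`RecordingIOError`.
    """
    if kind not in ("vsd", "laminar", "ecog"):
        raise ValueError(f"unknown recording kind {kind!r}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise RecordingIOError(f"cannot read {path}: {exc}") from exc
    try:
        if kind == "vsd":
            data = _require(f, "/vsd/data")[()]
            rate = float(_require(f, "/vsd/rate")[()])
            t0 = float(_require(f, "/vsd/t0")[()])
            geom = ArrayGeometry(
                positions=_require(f, "/vsd/positions")[()],
                spacing=float(_require(f, "/vsd/spacing")[()]),
                ring_channels=tuple(_require(f, "/vsd/ring_channels")[()]))
            return VSDRecording(data=data, rate=rate, geometry=geom, t0=t0)
        if kind == "laminar":
            g = _require(f, "/laminar")
            mua_grp = _require(f, "/laminar/mua")
            mua = [mua_grp[str(ch)][()]
                   for ch in range(len(mua_grp.keys()))]
            return LaminarRecording(
                lfp=_require(f, "/laminar/lfp")[()],
                mua_times=mua,
                rate=float(_require(f, "/laminar/rate")[()]),
                true_csd=_require(f, "/laminar/true_csd")[()],
                pitch=float(_require(f, "/laminar/pitch")[()]),
                mode=str(g.attrs.get("mode", "sync")),
                up_times=g["up_times"][()] if "up_times" in g else np.empty(0),
                sg_fraction=(float(g.attrs["sg_fraction"])
                             if "sg_fraction" in g.attrs else None))
        g = _require(f, "/ecog")
        labels = [s.decode() for s in _require(f, "/ecog/true_state_labels")[()]]
        episodes = []
        if "episode_state" in g:
            episodes = [(s.decode(), float(t), float(d)) for s, t, d in
                        zip(g["episode_state"][()], g["episode_start"][()],
                            g["episode_dur"][()])]
        return ECoGTrace(signal=_require(f, "/ecog/signal")[()],
                         rate=float(_require(f, "/ecog/rate")[()]),
                         band=tuple(_require(f, "/ecog/band")[()]),
                         true_state_labels=labels,
                         seg_len=float(g["seg_len"][()]) if "seg_len" in g else 2.0,
                         episodes=episodes)
    except KeyError as exc:
        raise SchemaError(f"missing dataset {exc}") from exc
    except OSError as exc:
        raise RecordingIOError(f"corrupt container {path}: {exc}") from exc
    finally:
        f.close()


def read_truth(path) -> GroundTruth:
    """Read the ground-truth group written next to a recording."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise RecordingIOError(f"cannot read {path}: {exc}") from exc
    with f:
        tg = _require(f, "/truth")
        return GroundTruth(
            state_labels=[s.decode() for s in tg["state_labels"][()]],
            wave_times=tg["wave_times"][()],
            wave_speeds=tg["wave_speeds"][()],
            wave_directions=tg["wave_directions"][()],
            laminar_sg_fraction=(float(tg.attrs["laminar_sg_fraction"])
                                 if "laminar_sg_fraction" in tg.attrs else None))
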