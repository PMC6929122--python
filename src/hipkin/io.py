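"""Columnar time-series I/O for recordings, angle traces, and configs.

Recordings are stored as CSV with columns ``time, gyro_x, gyro_y, gyro_z,
accel_x, accel_y, accel_z, mag_x, mag_y, mag_z`` or as HDF5 containers
with datasets of the same names (``time`` plus one (N, 3) dataset per
channel and an ``fs`` attribute).  Angle traces are CSV with columns
``time, fe, aa, ier, side``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .hip_angles import AngleTrace
from .preprocess import ImuRecording

__all__ = [
    "read_recording",
    "write_recording",
    "read_angles",
    "write_angles",
    "load_config",
]

_CHANNELS = ("gyro", "accel", "mag")
_AXES = ("x", "y", "z")


def write_recording(path, rec: ImuRecording) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time", data=rec.t)
            for ch in _CHANNELS:
                fh.create_dataset(ch, data=getattr(rec, ch))
            fh.attrs["fs"] = rec.fs
        return
    cols = {"time": rec.t}
    for ch in _CHANNELS:
        arr = getattr(rec, ch)
        for i, ax in enumerate(_AXES):
            cols[f"{ch}_{ax}"] = arr[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_recording(path, fs: float | None = None) -> ImuRecording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            t = np.asarray(fh["time"])
            chans = {ch: np.asarray(fh[ch]) for ch in _CHANNELS}
            fs = fs or float(fh.attrs["fs"])
        return ImuRecording(t=t, fs=fs, **chans)
    df = pd.read_csv(path)
    required = ["time"] + [f"{ch}_{ax}" for ch in _CHANNELS for ax in _AXES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    t = df["time"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.mean(np.diff(t)))
        fs = round(fs, 6)
    chans = {ch: df[[f"{ch}_{ax}" for ax in _AXES]].to_numpy() for ch in _CHANNELS}
    return ImuRecording(t=t, fs=fs, **chans)


def write_angles(path, trace: AngleTrace) -> None:
    pd.DataFrame({"time": trace.t, "fe": trace.fe, "aa": trace.aa,
                  "ier": trace.ier, "side": trace.side}).to_csv(path, index=False)


def read_angles(path) -> AngleTrace:
    df = pd.read_csv(path)
    missing = [c for c in ("time", "fe", "aa", "ier") if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    t = df["time"].to_numpy()
    side = str(df["side"].iloc[0]) if "side" in df.columns else "right"
    fs = round(1.0 / float(np.mean(np.diff(t))), 6)
    return AngleTrace(t=t, fe=df["fe"].to_numpy(), aa=df["aa"].to_numpy(),
                      ier=df["ier"].to_numpy(), side=side, fs=fs)


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            return json.load(fh)
        return yaml.safe_load(fh) or {}
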