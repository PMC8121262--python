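"""Reading and writing recordings and analysis artifacts.

Recordings are stored as an HDF5 file (dataset ``data``, attributes ``fs``,
``session_id``, ``animal_id``) with a JSON sidecar (same stem, ``.json``)
carrying the channel metadata and, for synthetic data, the ground truth.
Small fixtures can round-trip through CSV instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import pandas as pd

from .recording import Recording, make_channel_meta
from .synthetic import GroundTruth

__all__ = ["write_recording", "read_recording", "write_recording_csv",
           "read_recording_csv", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_recording(rec: Recording, path, truth: GroundTruth | None = None) -> Path:
    """Write a recording to HDF5 + JSON sidecar; returns the HDF5 path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["fs"] = rec.fs
        d.attrs["session_id"] = rec.session_id
        d.attrs["animal_id"] = rec.animal_id
    meta = {"channel_meta": rec.channel_meta.to_dict(orient="list"),
            "fs": rec.fs, "session_id": rec.session_id, "animal_id": rec.animal_id}
    if truth is not None:
        meta["ground_truth"] = truth.to_dict()
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path):
    """Read a recording written by :func:`write_recording`.

    Returns ``(recording, ground_truth_or_None)``.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        d = f["data"]
        data = d[()]
        fs = float(d.attrs["fs"])
        session_id = str(d.attrs.get("session_id", "session0"))
        animal_id = str(d.attrs.get("animal_id", "animal0"))
    meta = json.loads(sidecar_path(path).read_text())
    cm = meta["channel_meta"]
    channel_meta = make_channel_meta(cm["name"], cm["modality"], cm["region"])
    truth = None
    if "ground_truth" in meta:
        truth = GroundTruth.from_dict(meta["ground_truth"])
    return Recording(data, fs, channel_meta, session_id, animal_id), truth


def write_recording_csv(rec: Recording, path) -> Path:
    """CSV export for small fixtures: one column per channel, JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_meta["name"])
    df.to_csv(path, index=False)
    meta = {"channel_meta": rec.channel_meta.to_dict(orient="list"),
            "fs": rec.fs, "session_id": rec.session_id, "animal_id": rec.animal_id}
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording_csv(path) -> Recording:
    path = Path(path)
    meta = json.loads(sidecar_path(path).read_text())
    cm = meta["channel_meta"]
    df = pd.read_csv(path)
    data = df[cm["name"]].to_numpy().T
    return Recording(data, float(meta["fs"]),
                     make_channel_meta(cm["name"], cm["modality"], cm["region"]),
                     meta.get("session_id", "session0"),
                     meta.get("animal_id", "animal0"))
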