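"""HDF5 persistence for the pipeline's intermediate products."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .preproc import MEGRecording, SensorArray
from .telemetry import SpeedMatrix

__all__ = ["save_speeds", "load_speeds", "save_recording", "load_recording"]


def save_speeds(path: str | Path, speeds: SpeedMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=speeds.values)
        f.attrs["frame_rate"] = speeds.frame_rate
        f.attrs["normalised"] = speeds.normalised
        f.create_dataset("session_boundaries",
                         data=np.asarray(speeds.session_boundaries, dtype=int))
        f.create_dataset("keypoint_names",
                         data=np.array(speeds.keypoint_names, dtype="S"))


def load_speeds(path: str | Path) -> SpeedMatrix:
    with h5py.File(path, "r") as f:
        return SpeedMatrix(
            f["values"][()],
            float(f.attrs["frame_rate"]),
            bool(f.attrs["normalised"]),
            list(f["session_boundaries"][()]),
            [s.decode() for s in f["keypoint_names"][()]],
        )


def save_recording(path: str | Path, rec: MEGRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["sample_rate"] = rec.sample_rate
        f.create_dataset("positions", data=rec.array.positions)
        f.create_dataset("orientations", data=rec.array.orientations)
        f.create_dataset("channel_enabled", data=rec.array.channel_enabled)
        f.create_dataset("channel_names",
                         data=np.array(rec.array.channel_names, dtype="S"))
        g = f.create_group("triggers")
        for name, trig in rec.trigger_channels.items():
            g.create_dataset(name, data=trig)
        f.create_dataset("processing_log",
                         data=np.array(rec.processing_log, dtype="S"))


def load_recording(path: str | Path) -> MEGRecording:
    with h5py.File(path, "r") as f:
        array = SensorArray(
            f["positions"][()],
            f["orientations"][()],
            [s.decode() for s in f["channel_names"][()]],
            f["channel_enabled"][()].astype(bool),
        )
        triggers = {name: f["triggers"][name][()] for name in f["triggers"]}
        return MEGRecording(
            f["data"][()],
            float(f.attrs["sample_rate"]),
            array,
            triggers,
            [s.decode() for s in f["processing_log"][()]],
        )
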