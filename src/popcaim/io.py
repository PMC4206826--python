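"""File formats.

* Trace matrices: CSV (rows = cells, columns = frames, header row = frame
  timestamps in seconds) and HDF5 (datasets ``/traces``, ``/time``,
  ``/events``).
* Movies: multi-page TIFF, one file per channel, 16-bit unsigned.
* ROI sets and ground truth: JSON.
* Configuration: YAML mirroring the dataclass field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import Movie, ROISet
from .synthetic import StimulusEvent, TraceMatrix

__all__ = [
    "write_traces_csv", "read_traces_csv",
    "write_traces_h5", "read_traces_h5",
    "write_movie_tiff", "read_movie_tiff",
    "write_rois_json", "read_rois_json",
    "load_yaml_config", "dump_yaml_config",
]

_EVENT_DTYPE = [("time_s", "f8"), ("site", "S8"), ("frequency_hz", "f8"), ("n_pulses", "i8")]


def _events_to_array(events) -> np.ndarray:
    return np.array(
        [(e.time_s, e.site.encode(), e.frequency_hz, e.n_pulses) for e in events],
        dtype=_EVENT_DTYPE,
    )


def _events_from_array(arr) -> tuple:
    return tuple(
        StimulusEvent(float(r["time_s"]), r["site"].decode(),
                      float(r["frequency_hz"]), int(r["n_pulses"]))
        for r in arr
    )


def write_traces_csv(path, tm: TraceMatrix) -> None:
    df = pd.DataFrame(tm.data, index=tm.cell_ids, columns=np.round(tm.time, 6))
    df.index.name = "cell_id"
    df.to_csv(path)


def read_traces_csv(path, fps: float | None = None, events=()) -> TraceMatrix:
    df = pd.read_csv(path, index_col=0)
    time = df.columns.to_numpy(dtype=float)
    if fps is None:
        if len(time) < 2:
            raise ValueError("cannot infer fps from a single-frame CSV; pass fps")
        fps = 1.0 / float(np.mean(np.diff(time)))
    return TraceMatrix(df.to_numpy(dtype=float), fps=fps, events=tuple(events),
                       cell_ids=df.index.to_numpy())


def write_traces_h5(path, tm: TraceMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=tm.data)
        f.create_dataset("time", data=tm.time)
        f.create_dataset("events", data=_events_to_array(tm.events))
        f["traces"].attrs["fps"] = tm.fps
        f.create_dataset("cell_ids", data=np.asarray(tm.cell_ids))


def read_traces_h5(path) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        data = f["traces"][()]
        fps = float(f["traces"].attrs["fps"])
        events = _events_from_array(f["events"][()]) if "events" in f else ()
        cell_ids = f["cell_ids"][()] if "cell_ids" in f else None
    return TraceMatrix(data, fps=fps, events=events, cell_ids=cell_ids)


def write_movie_tiff(path, frames: np.ndarray) -> None:
    """One channel per file; frame index = time."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint16))


def read_movie_tiff(paths, fps: float, channel_names=None) -> Movie:
    """Assemble a multi-channel movie from per-channel TIFF stacks."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if channel_names is None:
        channel_names = ["green", "red"][: len(paths)]
    channels = {
        name: tifffile.imread(p) for name, p in zip(channel_names, paths)
    }
    return Movie(channels, fps=fps)


def write_rois_json(path, rois, extra: dict | None = None) -> None:
    records = rois.to_records() if isinstance(rois, ROISet) else list(rois)
    payload = {"cells": records}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_rois_json(path) -> ROISet:
    payload = json.loads(Path(path).read_text())
    return ROISet.from_records(payload["cells"])


def load_yaml_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must hold a YAML mapping")
    return cfg


def dump_yaml_config(path, cfg: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
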