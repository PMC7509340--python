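"""Reading and writing channel time series and simulated datasets.

Plain-CSV is the primary text interchange (a ``time`` column plus one column
per channel).  A minimal SNIRF-style HDF5 reader/writer over h5py covers the
common continuous-wave layout (``/nirs/data1/dataTimeSeries`` with a ``time``
vector); datasets are exported as a CSV bundle plus a ground-truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import ChannelTimeSeries

__all__ = [
    "read_csv_timeseries",
    "write_csv_timeseries",
    "read_snirf_timeseries",
    "write_snirf_timeseries",
    "write_dataset_bundle",
]


def write_csv_timeseries(ts: ChannelTimeSeries, path: str | Path) -> None:
    names = ts.channel_names or [f"ch{i}" for i in range(ts.n_channels)]
    frame = pd.DataFrame(ts.data, columns=list(names))
    frame.insert(0, "time", ts.times)
    frame.to_csv(path, index=False)


def read_csv_timeseries(path: str | Path, unit: str = "intensity") -> ChannelTimeSeries:
    frame = pd.read_csv(path)
    if "time" not in frame.columns:
        raise ValueError("CSV must contain a 'time' column")
    t = frame.pop("time").values
    if len(t) < 2:
        raise ValueError("need at least two samples to infer the sampling rate")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ChannelTimeSeries(
        frame.values, fs, unit=unit, channel_names=tuple(frame.columns)
    )


def write_snirf_timeseries(ts: ChannelTimeSeries, path: str | Path) -> None:
    """Write the minimal continuous-wave SNIRF-style HDF5 layout."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        d = f.create_group("nirs/data1")
        d.create_dataset("dataTimeSeries", data=ts.data)
        d.create_dataset("time", data=ts.times)


def read_snirf_timeseries(path: str | Path, unit: str = "intensity") -> ChannelTimeSeries:
    import h5py

    with h5py.File(path, "r") as f:
        data = np.asarray(f["nirs/data1/dataTimeSeries"])
        t = np.asarray(f["nirs/data1/time"])
    fs = 1.0 / float(np.median(np.diff(t)))
    return ChannelTimeSeries(data, fs, unit=unit)


def write_dataset_bundle(dataset, directory: str | Path) -> None:
    """Export a simulated group as per-subject CSVs plus a truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(dataset.config).items()
        },
        "active_roi": {
            "center_node": dataset.active_roi.center_node,
            "radius": dataset.active_roi.radius,
            "nodes": dataset.active_roi.node_ids.tolist(),
        },
        "null_roi": {
            "center_node": dataset.null_roi.center_node,
            "nodes": dataset.null_roi.node_ids.tolist(),
        },
        "subjects": [],
    }
    for i, subj in enumerate(dataset.subjects):
        for chromo, ts in subj.ts.items():
            write_csv_timeseries(
                ts, directory / f"subject{i + 1}_{chromo}.csv"
            )
        truth["subjects"].append(
            {
                "circumference": subj.error.circumference,
                "anchor_displacement": subj.error.anchor_displacement.tolist(),
                "attractor_displacements": subj.error.attractor_displacements.tolist(),
                "onsets": subj.onsets.tolist(),
                "blind_spot": subj.blind_spot,
            }
        )
    (directory / "truth.json").write_text(json.dumps(truth, indent=2))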