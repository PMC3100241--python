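"""File formats: spike CSV, bursts/IBI CSV, HDF5 voltage, spine CSV, JSON.

Spike CSV: columns electrode_id, time_s, times sorted within electrode.
Voltage HDF5: dataset "voltage_uv" (channels x samples) with attributes
sampling_rate_hz, duration_s and electrode_map. Ground truth travels as a
JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bursts import BurstTrain, burst_metric_table
from .detection import RawRecording, RecordingConfig, SpikeTrain
from .synthetic import GroundTruth, GroundTruthBurst

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_bursts_csv",
    "read_bursts_csv",
    "write_ibi_csv",
    "write_voltage_h5",
    "read_voltage_h5",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_spine_csv",
    "read_spine_csv",
    "write_json",
]


def write_spike_csv(trains: list[SpikeTrain], path) -> None:
    rows = [
        {"electrode_id": t.electrode_id, "time_s": ts}
        for t in trains
        for ts in t.times_s
    ]
    pd.DataFrame(rows, columns=["electrode_id", "time_s"]).to_csv(path, index=False)


def read_spike_csv(path, n_electrodes: int | None = None) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    by_el = {
        int(e): np.sort(sub["time_s"].to_numpy(dtype=float))
        for e, sub in df.groupby("electrode_id")
    }
    if n_electrodes is None:
        n_electrodes = (max(by_el) + 1) if by_el else 0
    return [
        SpikeTrain(electrode_id=e, times_s=by_el.get(e, np.empty(0)))
        for e in range(n_electrodes)
    ]


def write_bursts_csv(trains: list[BurstTrain], path) -> pd.DataFrame:
    table = burst_metric_table(trains)
    table.to_csv(path, index=False)
    return table


def read_bursts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ibi_csv(trains: list[BurstTrain], path) -> None:
    rows = [
        {"electrode_id": bt.electrode_id, "ibi_ms": v}
        for bt in trains
        for v in bt.ibis_ms
    ]
    pd.DataFrame(rows, columns=["electrode_id", "ibi_ms"]).to_csv(path, index=False)


def write_voltage_h5(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("voltage_uv", data=rec.voltage_uv)
        ds.attrs["sampling_rate_hz"] = rec.config.sampling_rate_hz
        ds.attrs["duration_s"] = rec.config.duration_s
        ds.attrs["n_electrodes"] = rec.config.n_electrodes
        ds.attrs["grid_rows"] = rec.config.grid_rows
        ds.attrs["grid_cols"] = rec.config.grid_cols
        ds.attrs["electrode_map"] = np.arange(rec.config.n_electrodes)


def read_voltage_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        ds = f["voltage_uv"]
        config = RecordingConfig(
            sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
            n_electrodes=int(ds.attrs["n_electrodes"]),
            grid_rows=int(ds.attrs.get("grid_rows", 8)),
            grid_cols=int(ds.attrs.get("grid_cols", 8)),
            duration_s=float(ds.attrs["duration_s"]),
        )
        return RawRecording(voltage_uv=ds[()], config=config)


def write_ground_truth_json(gt: GroundTruth, path) -> None:
    payload = {
        "mean_duration_ms": gt.mean_duration_ms,
        "mean_spikes_per_burst": gt.mean_spikes_per_burst,
        "spike_times_s": {str(e): list(map(float, t)) for e, t in gt.spike_times_s.items()},
        "bursts": [dataclasses.asdict(b) for b in gt.bursts],
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        spike_times_s={
            int(e): np.asarray(t, dtype=float)
            for e, t in payload["spike_times_s"].items()
        },
        bursts=[GroundTruthBurst(**b) for b in payload["bursts"]],
        mean_duration_ms=payload["mean_duration_ms"],
        mean_spikes_per_burst=payload["mean_spikes_per_burst"],
    )


def write_spine_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_spine_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "psd95" in df:
        df["psd95"] = df["psd95"].astype("boolean")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
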