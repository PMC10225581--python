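"""File interchange: HDF5 voltage containers, spike-timestamp CSV with JSON
sidecar metadata, and ground-truth JSON.

The voltage container is a single HDF5 file holding ``/voltage``
(electrodes x samples, float32 microvolts) with ``sampling_rate``,
``t0``, ``electrode_ids`` and optional ``layout`` attributes. Spike
trains travel as two-column delimited text (``electrode``, ``time_s``)
plus a ``<name>.meta.json`` sidecar carrying duration, electrode count
and detection provenance; round trips are lossless at float64 timestamp
precision (float32 for voltage).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import SpikeTrainSet, VoltageRecording
from .simulate import BurstWindow, GroundTruth, RecordingConfig, SimulationParams

__all__ = [
    "write_voltage",
    "read_voltage",
    "write_spike_csv",
    "read_spike_csv",
    "write_ground_truth",
    "read_ground_truth",
]

_VOLTAGE_DSET = "voltage"


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_voltage(rec: VoltageRecording, path: str | Path) -> Path:
    """Write a recording to the HDF5 voltage container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(_VOLTAGE_DSET, data=rec.samples.astype(np.float32))
        ds.attrs["units"] = "uV"
        f.attrs["sampling_rate"] = float(rec.sampling_rate)
        f.attrs["t0"] = float(rec.t0)
        f.attrs["electrode_ids"] = np.asarray(rec.electrode_ids, dtype=np.int64)
        if rec.layout is not None:
            f.attrs["layout"] = np.asarray(rec.layout, dtype=np.int64)
    return path


def read_voltage(path: str | Path) -> VoltageRecording:
    """Read a recording from the HDF5 voltage container, with validation."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if _VOLTAGE_DSET not in f:
            raise ValueError(f"{path}: missing '/{_VOLTAGE_DSET}' dataset")
        if "sampling_rate" not in f.attrs:
            raise ValueError(f"{path}: missing 'sampling_rate' attribute")
        samples = np.asarray(f[_VOLTAGE_DSET], dtype=float)
        layout = f.attrs.get("layout")
        rec = VoltageRecording(
            samples=samples,
            sampling_rate=float(f.attrs["sampling_rate"]),
            t0=float(f.attrs.get("t0", 0.0)),
            electrode_ids=list(f.attrs["electrode_ids"]) if "electrode_ids" in f.attrs else None,
            layout=tuple(int(v) for v in layout) if layout is not None else None,
        )
    return rec


def write_spike_csv(
    trains: SpikeTrainSet, path: str | Path, write_metadata: bool = True
) -> Path:
    """Write spike trains as (electrode, time_s) delimited text.

    A JSON sidecar next to the CSV records duration, t0, electrode count
    and the train set's provenance metadata (per-electrode sigma etc.).
    """
    path = Path(path)
    rows = [
        (e, t)
        for e, times in enumerate(trains.trains)
        for t in times
    ]
    df = pd.DataFrame(rows, columns=["electrode", "time_s"])
    df["electrode"] = df["electrode"].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")
    if write_metadata:
        meta = {
            "duration": trains.duration,
            "t0": trains.t0,
            "n_electrodes": trains.n_electrodes,
            "meta": _jsonable(trains.meta),
        }
        _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_spike_csv(
    path: str | Path,
    duration: float | None = None,
    n_electrodes: int | None = None,
) -> SpikeTrainSet:
    """Read a spike CSV (with optional JSON sidecar) into a SpikeTrainSet.

    Strict schema: exactly the ``electrode`` and ``time_s`` columns,
    integer electrode indices >= 0, finite non-negative times. Unsorted
    rows are accepted, sorted on load with a warning; duplicate
    timestamps on one electrode are collapsed (also with a warning).
    ``duration``/``n_electrodes`` fall back to the sidecar and finally to
    the data themselves.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"electrode", "time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if df["electrode"].isna().any() or df["time_s"].isna().any():
        raise ValueError(f"{path}: malformed rows (missing values)")
    electrodes = df["electrode"].to_numpy()
    if not np.allclose(electrodes, np.round(electrodes)) or (electrodes < 0).any():
        raise ValueError(f"{path}: electrode ids must be non-negative integers")
    times = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(times)) or (times < 0).any():
        raise ValueError(f"{path}: spike times must be finite and non-negative")

    meta: dict = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    if duration is None:
        duration = meta.get("duration")
    if duration is None:
        duration = float(times.max()) if times.size else 1.0
    t0 = float(meta.get("t0", 0.0))
    if n_electrodes is None:
        n_electrodes = meta.get("n_electrodes")
    if n_electrodes is None:
        n_electrodes = int(electrodes.max()) + 1 if electrodes.size else 0

    trains: list[np.ndarray] = []
    for e in range(int(n_electrodes)):
        t = times[electrodes.astype(int) == e]
        if t.size and np.any(np.diff(t) < 0):
            warnings.warn(f"{path}: unsorted spike times on electrode {e}; sorting")
            t = np.sort(t)
        else:
            t = np.sort(t)  # cheap no-op when already sorted
        if t.size and np.any(np.diff(t) == 0):
            warnings.warn(f"{path}: duplicate timestamps on electrode {e}; collapsing")
            t = np.unique(t)
        trains.append(t)
    return SpikeTrainSet(
        trains=trains, duration=float(duration), t0=t0, meta=meta.get("meta", {})
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Serialize simulator ground truth (spikes, bursts, parameters) to JSON."""
    path = Path(path)
    payload = {
        "spike_times": [t.tolist() for t in truth.spike_times],
        "burst_windows": [
            {"start": w.start, "end": w.end, "electrodes": list(w.electrodes)}
            for w in truth.burst_windows
        ],
        "params": _jsonable(asdict(truth.params)),
        "config": _jsonable(asdict(truth.config)),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    params = dict(payload["params"])
    if isinstance(params.get("background_rate"), list):
        params["background_rate"] = tuple(params["background_rate"])
    config = dict(payload["config"])
    config["layout"] = tuple(config["layout"])
    return GroundTruth(
        spike_times=[np.asarray(t, dtype=float) for t in payload["spike_times"]],
        burst_windows=[
            BurstWindow(start=w["start"], end=w["end"], electrodes=tuple(w["electrodes"]))
            for w in payload["burst_windows"]
        ],
        params=SimulationParams(**params),
        config=RecordingConfig(**config),
    )
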