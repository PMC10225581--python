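"""End-to-end pipeline: detection -> network metrics -> group statistics.

`run_pipeline` takes wells grouped by condition label (voltage
containers, spike CSVs, or in-memory objects), runs each through the
analysis chain with one shared parameter set, and returns per-well
metrics, burst tables, a ROUT+ANOVA comparison per metric, and a
machine-readable run manifest echoing every tunable. Identical config
and inputs always give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .core import ConfigError, SpikeTrainSet, VoltageRecording
from .detection import DetectorParams, FilterSpec, detect_all
from .io import read_spike_csv, read_voltage
from .network import (
    NORMALIZED_FIELDS,
    BurstParams,
    compute_well_metrics,
)
from .stats import compare_groups

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_METRIC_COLUMNS = (
    "mean_firing_rate",
    "sb_frequency",
    "mean_sb_interval",
    "mean_sb_duration",
    "mean_spikes_per_sb",
    "max_asdr",
    "n_active_electrodes",
)


@dataclass
class PipelineConfig:
    """All tunables of one analysis run; YAML round-trip stable.

    Defaults mirror the standard acquisition/analysis parameters:
    200–3000 Hz band-pass, 5.5 x sigma detection threshold, 200 ms ASDR
    bins, 1.25 SD envelope threshold with 200 ms merge distance and 35%
    electrode participation, ROUT at Q = 10%.
    """

    filter: FilterSpec = field(default_factory=FilterSpec)
    detector: DetectorParams = field(default_factory=DetectorParams)
    burst: BurstParams = field(default_factory=BurstParams)
    bin_width: float = 0.2
    control_label: str | None = None
    rout: bool = True
    rout_q: float = 0.10
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        self.burst.validate(self.bin_width)
        if not 0 < self.rout_q < 1:
            raise ConfigError("rout_q must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], Mapping):
            d["filter"] = FilterSpec(**d["filter"])
        if "detector" in d and isinstance(d["detector"], Mapping):
            d["detector"] = DetectorParams(**d["detector"])
        if "burst" in d and isinstance(d["burst"], Mapping):
            d["burst"] = BurstParams(**d["burst"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    well_metrics: pd.DataFrame
    burst_tables: dict[str, pd.DataFrame]
    comparisons: dict[str, dict]
    normalized: pd.DataFrame | None
    manifest: dict


WellInput = "VoltageRecording | SpikeTrainSet | str | Path"


def _load_well(source, config: PipelineConfig) -> SpikeTrainSet:
    if isinstance(source, SpikeTrainSet):
        return source
    if isinstance(source, VoltageRecording):
        return detect_all(source, config.filter, config.detector)
    path = Path(source)
    if path.suffix in {".h5", ".hdf5"}:
        return detect_all(read_voltage(path), config.filter, config.detector)
    if path.suffix == ".csv":
        return read_spike_csv(path)
    raise ConfigError(f"cannot infer well input type from {path}")


def run_pipeline(
    config: PipelineConfig,
    inputs: Mapping[str, Sequence],
) -> PipelineResult:
    """Analyse wells grouped by condition label.

    ``inputs`` maps condition label -> sequence of wells, each a
    VoltageRecording, SpikeTrainSet, or a path to a voltage container
    (``.h5``) or spike CSV. All wells must share one sampling rate.
    Writes metrics/bursts/comparison/manifest files when
    ``config.output_dir`` is set.
    """
    if not inputs:
        raise ConfigError("no inputs given")
    rows: list[dict] = []
    burst_tables: dict[str, pd.DataFrame] = {}
    sampling_rates: set[float] = set()
    for label, wells in inputs.items():
        for i, source in enumerate(wells):
            if isinstance(source, VoltageRecording):
                sampling_rates.add(float(source.sampling_rate))
            elif isinstance(source, (str, Path)) and Path(source).suffix in {".h5", ".hdf5"}:
                source = read_voltage(source)
                sampling_rates.add(float(source.sampling_rate))
            if len(sampling_rates) > 1:
                raise ConfigError(f"mixed sampling rates across wells: {sorted(sampling_rates)}")
            trains = _load_well(source, config)
            metrics, bursts, _ = compute_well_metrics(trains, config.bin_width, config.burst)
            well_id = f"{label}/{i}"
            row = {"condition": label, "well": well_id}
            row.update({k: metrics.as_dict()[k] for k in _METRIC_COLUMNS})
            rows.append(row)
            burst_tables[well_id] = pd.DataFrame(
                [
                    {
                        "start_s": b.start,
                        "end_s": b.end,
                        "n_electrodes": len(b.electrodes),
                        "spikes": b.spike_count,
                        "peak_asdr": b.peak_asdr,
                    }
                    for b in bursts
                ],
                columns=["start_s", "end_s", "n_electrodes", "spikes", "peak_asdr"],
            )
    well_df = pd.DataFrame(rows)

    comparisons: dict[str, dict] = {}
    if well_df["condition"].nunique() >= 2:
        for metric in _METRIC_COLUMNS[:-1]:
            groups = {
                label: sub[metric].dropna().to_numpy(dtype=float)
                for label, sub in well_df.groupby("condition", sort=True)
            }
            comparisons[metric] = compare_groups(groups, q=config.rout_q, rout=config.rout)

    normalized = None
    if config.control_label is not None:
        if config.control_label not in inputs:
            raise ConfigError(f"unknown control condition label {config.control_label!r}")
        control_means = (
            well_df[well_df["condition"] == config.control_label][list(NORMALIZED_FIELDS)]
            .mean(numeric_only=True)
        )
        norm_rows = []
        for _, row in well_df.iterrows():
            out = {"condition": row["condition"], "well": row["well"]}
            for name in NORMALIZED_FIELDS:
                ref = control_means.get(name)
                value = row[name]
                if ref is None or pd.isna(ref) or ref == 0 or pd.isna(value):
                    out[name] = None
                else:
                    out[name] = 100.0 * value / ref
            norm_rows.append(out)
        normalized = pd.DataFrame(norm_rows)

    manifest = {
        "package": "meaburst",
        "version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "inputs": {label: len(wells) for label, wells in inputs.items()},
        "seed": config.seed,
    }

    result = PipelineResult(
        well_metrics=well_df,
        burst_tables=burst_tables,
        comparisons=comparisons,
        normalized=normalized,
        manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.well_metrics.to_csv(out_dir / "well_metrics.csv", index=False)
    bursts_dir = out_dir / "bursts"
    bursts_dir.mkdir(exist_ok=True)
    for well_id, table in result.burst_tables.items():
        table.to_csv(bursts_dir / (well_id.replace("/", "_") + ".csv"), index=False)
    if result.normalized is not None:
        result.normalized.to_csv(out_dir / "percent_of_control.csv", index=False)
    comparisons = {
        metric: {
            **{k: v for k, v in comp.items() if k != "anova"},
            "anova": asdict(comp["anova"]) if comp["anova"] is not None else None,
        }
        for metric, comp in result.comparisons.items()
    }
    (out_dir / "comparisons.json").write_text(json.dumps(comparisons, indent=1))
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
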