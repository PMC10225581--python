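"""Shared data containers for multielectrode-array (MEA) analysis.

Two objects travel through the whole pipeline: :class:`VoltageRecording`
(the raw/filtered extracellular trace matrix of one well) and
:class:`SpikeTrainSet` (per-electrode spike timestamps), the hinge between
spike detection and network-level analysis. Units are microvolts and
seconds throughout; electrodes are indexed 0-based, row-major over the
well's electrode grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VoltageRecording",
    "SpikeTrainSet",
    "ConfigError",
    "InfeasibleParamsError",
    "UndefinedMetricError",
    "SpanMismatchError",
]


class ConfigError(ValueError):
    """A parameter set is internally inconsistent (e.g. cutoff above Nyquist)."""


class InfeasibleParamsError(ValueError):
    """Simulation parameters that cannot produce a valid recording."""


class UndefinedMetricError(ValueError):
    """A summary metric is undefined for the given data (signalled, never 0)."""


class SpanMismatchError(ValueError):
    """Two objects that must cover the same time span do not."""


@dataclass
class VoltageRecording:
    """Multi-channel extracellular voltage matrix with sampling metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_electrodes, n_samples)
        Voltage in microvolts.
    sampling_rate : float
        Samples per second per channel (Hz).
    t0 : float
        Time of the first sample, seconds.
    electrode_ids : sequence of int, optional
        Defaults to ``0 .. n_electrodes-1``.
    layout : (rows, cols), optional
        Electrode grid geometry; must multiply out to ``n_electrodes``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    electrode_ids: Sequence[int] | None = None
    layout: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigError("samples must be a 2-D (electrodes x time) array")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("voltage samples must be finite")
        n = self.samples.shape[0]
        if self.electrode_ids is None:
            self.electrode_ids = list(range(n))
        else:
            self.electrode_ids = [int(e) for e in self.electrode_ids]
            if len(self.electrode_ids) != n:
                raise ConfigError("electrode_ids length must match electrode count")
        if self.layout is not None:
            rows, cols = self.layout
            if rows * cols != n:
                raise ConfigError("layout rows*cols must equal electrode count")
            self.layout = (int(rows), int(cols))

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike timestamps over a recording of known length.

    ``trains[i]`` holds the spike times (seconds, strictly increasing) of
    electrode ``i``; all times lie in ``[t0, t0 + duration]``. ``meta``
    carries provenance such as the per-electrode noise estimate sigma and
    the detector parameters that produced the trains.
    """

    trains: list[np.ndarray]
    duration: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        clean: list[np.ndarray] = []
        hi = self.t0 + self.duration + 1e-9
        for i, t in enumerate(self.trains):
            t = np.asarray(t, dtype=float).ravel()
            if t.size and not np.all(np.diff(t) > 0):
                raise ConfigError(f"electrode {i}: spike times not strictly increasing")
            if t.size and (t[0] < self.t0 - 1e-9 or t[-1] > hi):
                raise ConfigError(f"electrode {i}: spike times outside recording span")
            clean.append(t)
        self.trains = clean

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        """Spike count per electrode."""
        return np.array([t.size for t in self.trains], dtype=int)

    @property
    def total_spikes(self) -> int:
        return int(self.counts().sum())

    def rates(self) -> np.ndarray:
        """Mean firing rate per electrode, Hz."""
        return self.counts() / self.duration

    def active_mask(self, min_rate_per_min: float = 5.0) -> np.ndarray:
        """Boolean mask of electrodes firing at >= ``min_rate_per_min`` spikes/min.

        Five spikes per minute is a common vendor default for calling an
        electrode active; inactive electrodes are excluded from rate
        averages and from the burst-participation denominator.
        """
        return self.rates() * 60.0 >= min_rate_per_min

    def all_times(self) -> np.ndarray:
        """All spike times pooled across electrodes (unsorted concatenation)."""
        if not self.trains:
            return np.empty(0)
        return np.concatenate(self.trains) if self.total_spikes else np.empty(0)
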