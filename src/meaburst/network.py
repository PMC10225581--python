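"""Array-wide spike detection rate (ASDR) and synchronized-burst analysis.

The ASDR is the spike count summed over all electrodes per fixed time
bin (200 ms by default); its time series reveals network events. A
synchronized burst (SB) is detected with an envelope-style rule:

1. bins whose count exceeds mean + 1.25 SD of the ASDR are burst seeds;
2. each seed run is extended left and right until the count falls back
   to or below the mean (the envelope edges);
3. bursts separated by less than 200 ms are merged;
4. a burst is retained only if at least 35% of the *active* electrodes
   (>= 5 spikes/min by default) contribute at least one spike inside it.

Well-level summary metrics (mean firing rate, SB frequency / interval /
duration, spikes per SB, maximum ASDR) and percent-of-control
normalization complete the analysis layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .core import ConfigError, SpanMismatchError, SpikeTrainSet, UndefinedMetricError

__all__ = [
    "ASDRSeries",
    "BurstParams",
    "SynchronizedBurst",
    "WellMetrics",
    "compute_asdr",
    "detect_synchronized_bursts",
    "mean_firing_rate",
    "burst_metrics",
    "compute_well_metrics",
    "percent_of_control",
    "NORMALIZED_FIELDS",
]


@dataclass
class ASDRSeries:
    """Binned array-wide spike counts; the substrate of burst detection."""

    counts: np.ndarray
    bin_width: float = 0.2
    start: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if np.any(self.counts < 0):
            raise ConfigError("ASDR counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def span(self) -> float:
        """Covered time span, seconds (trailing partial bin excluded)."""
        return self.n_bins * self.bin_width

    def edges(self) -> np.ndarray:
        return self.start + np.arange(self.n_bins + 1) * self.bin_width


@dataclass(frozen=True)
class BurstParams:
    """Envelope synchronized-burst detector parameters."""

    envelope_threshold_sd: float = 1.25
    min_separation: float = 0.2
    min_electrode_fraction: float = 0.35
    active_electrode_min_rate: float = 5.0  # spikes/min
    smoothing: int | None = None  # moving-average width, bins; None = raw

    def validate(self, bin_width: float) -> None:
        if not 0 < self.min_electrode_fraction <= 1:
            raise ConfigError("min_electrode_fraction must lie in (0, 1]")
        if self.min_separation < bin_width:
            raise ConfigError("min_separation must be >= the ASDR bin width")
        if self.smoothing is not None and self.smoothing < 1:
            raise ConfigError("smoothing width must be >= 1 bin")


@dataclass(frozen=True)
class SynchronizedBurst:
    """One detected network burst (times are ASDR bin edges)."""

    start: float
    end: float
    electrodes: frozenset[int]
    spike_count: int
    peak_asdr: int

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class WellMetrics:
    """Per-well summary of excitability and network synchrony.

    SB-derived fields are ``None`` (absent, not zero) when undefined:
    every SB statistic when no burst was detected, and the inter-burst
    interval when fewer than two were.
    """

    mean_firing_rate: float | None = None  # Hz, over active electrodes
    sb_frequency: float = 0.0  # SBs per minute
    mean_sb_interval: float | None = None  # s, end-to-next-start gap
    mean_sb_duration: float | None = None  # s
    mean_spikes_per_sb: float | None = None
    max_asdr: int | None = None  # spikes per bin, per-recording max
    n_active_electrodes: int = 0

    def as_dict(self) -> dict[str, float | int | None]:
        return dict(self.__dict__)


def compute_asdr(trains: SpikeTrainSet, bin_width: float = 0.2) -> ASDRSeries:
    """Bin all spikes (all electrodes pooled) into fixed-width bins.

    ``counts[k]`` counts spikes with ``k*w <= t - t0 < (k+1)*w``; the
    trailing partial bin is dropped.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    n_bins = int(math.floor(trains.duration / bin_width + 1e-9))
    if n_bins == 0:
        return ASDRSeries(counts=np.empty(0, dtype=int), bin_width=bin_width, start=trains.t0)
    t = trains.all_times()
    idx = np.floor((t - trains.t0) / bin_width).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return ASDRSeries(counts=counts, bin_width=bin_width, start=trains.t0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive bin indices."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def detect_synchronized_bursts(
    asdr: ASDRSeries,
    trains: SpikeTrainSet,
    params: BurstParams = BurstParams(),
) -> list[SynchronizedBurst]:
    """Detect synchronized bursts from an ASDR series and its spike trains.

    Implements the envelope rule described in the module docstring. The
    ASDR must have been computed from ``trains`` (same origin and span).
    An all-equal ASDR has zero variance and yields no bursts.
    """
    params.validate(asdr.bin_width)
    if abs(asdr.start - trains.t0) > 1e-9 or asdr.span > trains.duration + 1e-9:
        raise SpanMismatchError("ASDR series does not cover the span of the spike trains")
    counts = asdr.counts
    if counts.size == 0:
        return []
    det = counts.astype(float)
    if params.smoothing is not None and params.smoothing > 1:
        kernel = np.ones(params.smoothing) / params.smoothing
        det = np.convolve(det, kernel, mode="same")
    mu = det.mean()
    sd = det.std()
    if sd == 0:
        return []
    seed_mask = det > mu + params.envelope_threshold_sd * sd
    above = det > mu
    # envelope extension: a burst is a maximal above-mean run containing a seed
    intervals = [
        (a, b) for a, b in _runs(above) if seed_mask[a : b + 1].any()
    ]
    if not intervals:
        return []
    # bin indices -> times at bin edges
    w = asdr.bin_width
    windows = [(asdr.start + a * w, asdr.start + (b + 1) * w) for a, b in intervals]
    # merge bursts separated by less than min_separation
    merged: list[list[float]] = [list(windows[0])]
    for s, e in windows[1:]:
        if s - merged[-1][1] < params.min_separation - 1e-12:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    active = trains.active_mask(params.active_electrode_min_rate)
    n_active = int(active.sum())
    if n_active == 0:
        return []

    bursts: list[SynchronizedBurst] = []
    for s, e in merged:
        participating = frozenset(
            i
            for i, t in enumerate(trains.trains)
            if t.size and np.any((t >= s) & (t < e))
        )
        n_part_active = sum(1 for i in participating if active[i])
        if n_part_active / n_active < params.min_electrode_fraction - 1e-12:
            continue
        spike_count = int(
            sum(np.count_nonzero((t >= s) & (t < e)) for t in trains.trains)
        )
        a = int(round((s - asdr.start) / w))
        b = int(round((e - asdr.start) / w))
        peak = int(counts[a:b].max())
        bursts.append(
            SynchronizedBurst(
                start=float(s),
                end=float(e),
                electrodes=participating,
                spike_count=spike_count,
                peak_asdr=peak,
            )
        )
    return bursts


def mean_firing_rate(
    trains: SpikeTrainSet,
    duration: float | None = None,
    active_only: bool = True,
    active_min_rate: float = 5.0,
) -> float:
    """Mean spikes/s per included electrode.

    With ``active_only`` (default) the average runs over electrodes firing
    at >= ``active_min_rate`` spikes/min; with no included electrode the
    metric is undefined and :class:`UndefinedMetricError` is raised
    (never silently 0).
    """
    duration = trains.duration if duration is None else duration
    if duration <= 0:
        raise ConfigError("duration must be positive")
    counts = trains.counts()
    if active_only:
        mask = counts / duration * 60.0 >= active_min_rate
    else:
        mask = np.ones(trains.n_electrodes, dtype=bool)
    if not mask.any():
        raise UndefinedMetricError("no included electrodes: mean firing rate undefined")
    return float(np.mean(counts[mask] / duration))


def burst_metrics(
    bursts: list[SynchronizedBurst],
    duration: float,
    asdr: ASDRSeries | None = None,
) -> WellMetrics:
    """Summary statistics of a detected burst list.

    ``sb_frequency`` is bursts/min; durations and intervals are means in
    seconds, the interval being the end-to-next-start gap. ``max_asdr``
    is the per-recording maximum bin count of ``asdr`` when provided.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    bursts = sorted(bursts, key=lambda b: b.start)
    m = WellMetrics(sb_frequency=len(bursts) / duration * 60.0)
    if asdr is not None and asdr.n_bins:
        m.max_asdr = int(asdr.counts.max())
    if bursts:
        m.mean_sb_duration = float(np.mean([b.duration for b in bursts]))
        m.mean_spikes_per_sb = float(np.mean([b.spike_count for b in bursts]))
    if len(bursts) >= 2:
        gaps = [b2.start - b1.end for b1, b2 in zip(bursts[:-1], bursts[1:])]
        m.mean_sb_interval = float(np.mean(gaps))
    return m


def compute_well_metrics(
    trains: SpikeTrainSet,
    bin_width: float = 0.2,
    params: BurstParams = BurstParams(),
) -> tuple[WellMetrics, list[SynchronizedBurst], ASDRSeries]:
    """Full network-analysis chain for one well: ASDR -> bursts -> metrics."""
    asdr = compute_asdr(trains, bin_width)
    bursts = detect_synchronized_bursts(asdr, trains, params)
    metrics = burst_metrics(bursts, trains.duration, asdr)
    metrics.n_active_electrodes = int(trains.active_mask(params.active_electrode_min_rate).sum())
    try:
        metrics.mean_firing_rate = mean_firing_rate(
            trains, active_only=True, active_min_rate=params.active_electrode_min_rate
        )
    except UndefinedMetricError:
        metrics.mean_firing_rate = None
    return metrics, bursts, asdr


#: Metrics reported as percent of control in group comparisons
#: (the firing rate is conventionally reported in absolute Hz).
NORMALIZED_FIELDS = (
    "sb_frequency",
    "mean_sb_interval",
    "mean_sb_duration",
    "mean_spikes_per_sb",
    "max_asdr",
)


def percent_of_control(
    metrics: WellMetrics | Mapping[str, float | None],
    control: WellMetrics | Mapping[str, float | None],
    fields: Iterable[str] = NORMALIZED_FIELDS,
) -> tuple[dict[str, float], list[str]]:
    """Express metrics as 100 x value / control value, field by field.

    Returns ``(normalized, non_normalizable)``: fields whose control value
    is absent or zero cannot be normalized and are flagged by name instead
    of being silently dropped or zeroed.
    """
    mdict = metrics.as_dict() if isinstance(metrics, WellMetrics) else dict(metrics)
    cdict = control.as_dict() if isinstance(control, WellMetrics) else dict(control)
    out: dict[str, float] = {}
    flagged: list[str] = []
    for name in fields:
        value = mdict.get(name)
        ref = cdict.get(name)
        if ref is None or ref == 0 or value is None:
            flagged.append(name)
        else:
            out[name] = 100.0 * float(value) / float(ref)
    return out, flagged
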