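"""ASDR construction, envelope burst detection and well-metric tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meaburst import (
    ASDRSeries,
    BurstParams,
    SpanMismatchError,
    SpikeTrainSet,
    SynchronizedBurst,
    UndefinedMetricError,
    burst_metrics,
    compute_asdr,
    compute_well_metrics,
    detect_synchronized_bursts,
    mean_firing_rate,
    percent_of_control,
)
from meaburst.network import WellMetrics


def train_set(spikes_by_electrode, duration):
    return SpikeTrainSet(
        trains=[np.asarray(t, dtype=float) for t in spikes_by_electrode],
        duration=duration,
    )


class TestASDR:
    def test_hand_binned_example(self):
        trains = train_set([[0.05, 0.25], [0.15]], duration=0.4)
        asdr = compute_asdr(trains, bin_width=0.2)
        assert asdr.counts.tolist() == [2, 1]

    def test_empty_trains_all_zero_bins(self):
        asdr = compute_asdr(train_set([[]], duration=1.0), bin_width=0.2)
        assert asdr.counts.tolist() == [0, 0, 0, 0, 0]

    def test_trailing_partial_bin_dropped(self):
        trains = train_set([[0.45]], duration=0.5)
        asdr = compute_asdr(trains, bin_width=0.2)
        assert asdr.n_bins == 2  # the spike at 0.45 s falls off the covered span
        assert asdr.counts.sum() == 0

    @given(
        st.lists(
            st.lists(st.floats(0.0, 9.99), max_size=40),
            min_size=1,
            max_size=6,
        )
    )
    def test_conservation_of_spike_counts(self, raw):
        """Summed bin counts equal a direct count of spikes in the covered
        span, for arbitrary train sets."""
        trains = train_set(
            [np.unique(np.asarray(t, dtype=float)) for t in raw], duration=10.0
        )
        asdr = compute_asdr(trains, bin_width=0.3)
        span = asdr.n_bins * 0.3
        direct = sum(int(np.count_nonzero(t < span)) for t in trains.trains)
        assert int(asdr.counts.sum()) == direct


class TestBurstDetection:
    def test_constant_asdr_has_no_bursts(self):
        # one spike every 100 ms -> every 200 ms bin holds exactly 2 spikes
        t = np.arange(0.05, 10.0, 0.1)
        trains = train_set([t], duration=10.0)
        asdr = compute_asdr(trains)
        assert asdr.counts.std() == 0
        assert detect_synchronized_bursts(asdr, trains) == []

    def test_span_mismatch_rejected(self):
        trains = train_set([[0.5]], duration=1.0)
        other = ASDRSeries(counts=np.zeros(50, dtype=int), bin_width=0.2)
        with pytest.raises(SpanMismatchError):
            detect_synchronized_bursts(other, trains)

    def test_recovers_ground_truth_bursts(self, sync_fixture, sync_trains):
        """Detected burst count within +/-1 of truth; every detected window
        overlaps exactly one true window."""
        _, truth = sync_fixture
        asdr = compute_asdr(sync_trains)
        bursts = detect_synchronized_bursts(asdr, sync_trains)
        assert abs(len(bursts) - len(truth.burst_windows)) <= 1
        for b in bursts:
            hits = [
                w for w in truth.burst_windows
                if min(b.end, w.end) > max(b.start, w.start)
            ]
            assert len(hits) == 1

    def test_asynchronous_well_yields_few_bursts(self, sync_trains, hyper_trains):
        """Despite a higher total spike count, the desynchronized well shows
        no clear synchronized-burst pattern."""
        assert hyper_trains.total_spikes > sync_trains.total_spikes
        n_sync = len(detect_synchronized_bursts(compute_asdr(sync_trains), sync_trains))
        n_hyper = len(detect_synchronized_bursts(compute_asdr(hyper_trains), hyper_trains))
        assert n_hyper < 0.5 * n_sync

    def test_participation_filter_uses_active_electrodes(self):
        """A count surge carried by a single electrode is not a network
        burst when many electrodes are active."""
        rng = np.random.default_rng(0)
        # 10 active electrodes firing sparsely, electrode 0 adds a surge
        trains = [np.sort(rng.uniform(0, 60.0, 12)) for _ in range(10)]
        trains[0] = np.unique(np.concatenate([trains[0], 10.0 + np.arange(50) * 0.004]))
        ts = train_set(trains, duration=60.0)
        bursts = detect_synchronized_bursts(compute_asdr(ts), ts)
        assert bursts == []

    def test_raising_min_separation_never_increases_burst_count(self, sync_trains):
        asdr = compute_asdr(sync_trains)
        counts = [
            len(detect_synchronized_bursts(asdr, sync_trains,
                                           BurstParams(min_separation=sep)))
            for sep in (0.2, 0.4, 0.8, 1.6, 3.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_boundaries_within_one_bin_of_truth(self, sync_fixture, sync_trains):
        _, truth = sync_fixture
        asdr = compute_asdr(sync_trains)
        bursts = detect_synchronized_bursts(asdr, sync_trains)
        errors = []
        for w in truth.burst_windows:
            overlapping = [
                b for b in bursts if min(b.end, w.end) > max(b.start, w.start)
            ]
            if overlapping:
                b = overlapping[0]
                errors.append(max(abs(b.start - w.start), abs(b.end - w.end)))
        assert errors and float(np.mean(errors)) <= 0.2 + 1e-9


class TestMetrics:
    def test_single_electrode_rate(self):
        trains = train_set([np.linspace(0.5, 99.5, 100)], duration=100.0)
        assert mean_firing_rate(trains) == pytest.approx(1.0)

    def test_empty_trains_all_electrodes_included(self):
        trains = train_set([[] for _ in range(16)], duration=10.0)
        assert mean_firing_rate(trains, active_only=False) == 0.0

    def test_no_active_electrodes_is_undefined_not_zero(self):
        trains = train_set([[] for _ in range(16)], duration=10.0)
        with pytest.raises(UndefinedMetricError):
            mean_firing_rate(trains, active_only=True)

    def test_poisson_rate_recovery_single_well(self):
        from meaburst import RecordingConfig, SimulationParams, simulate_spike_trains

        trains, _ = simulate_spike_trains(
            RecordingConfig(duration=300.0),
            SimulationParams(background_rate=2.0, rng_seed=42),
        )
        se = np.sqrt(2.0 / 300.0) / 4.0  # 16 electrodes
        assert abs(mean_firing_rate(trains) - 2.0) <= 3 * se

    def test_hand_computed_burst_metrics(self):
        bursts = [
            SynchronizedBurst(1.0, 2.0, frozenset({0, 1}), 10, 5),
            SynchronizedBurst(4.0, 5.0, frozenset({0, 1}), 20, 8),
        ]
        m = burst_metrics(bursts, duration=60.0)
        assert m.sb_frequency == pytest.approx(2.0)
        assert m.mean_sb_duration == pytest.approx(1.0)
        assert m.mean_sb_interval == pytest.approx(2.0)
        assert m.mean_spikes_per_sb == pytest.approx(15.0)

    def test_no_bursts_fields_absent_not_zero(self):
        m = burst_metrics([], duration=60.0)
        assert m.sb_frequency == 0.0
        assert m.mean_sb_duration is None
        assert m.mean_sb_interval is None
        assert m.mean_spikes_per_sb is None

    def test_single_burst_interval_absent(self):
        m = burst_metrics([SynchronizedBurst(1.0, 2.0, frozenset({0}), 5, 3)],
                          duration=30.0)
        assert m.sb_frequency == pytest.approx(2.0)
        assert m.mean_sb_interval is None

    def test_well_metrics_composition(self, sync_trains):
        metrics, bursts, asdr = compute_well_metrics(sync_trains)
        assert metrics.max_asdr == int(asdr.counts.max())
        assert metrics.sb_frequency == pytest.approx(len(bursts) / 60.0 * 60.0)
        assert metrics.n_active_electrodes == 16


class TestPercentOfControl:
    def test_doubling_and_identity(self):
        m = WellMetrics(sb_frequency=2.0, max_asdr=10)
        c = WellMetrics(sb_frequency=1.0, max_asdr=10)
        norm, flagged = percent_of_control(m, c)
        assert norm["sb_frequency"] == pytest.approx(200.0)
        assert norm["max_asdr"] == pytest.approx(100.0)

    def test_absent_control_flagged_not_normalized(self):
        m = WellMetrics(sb_frequency=2.0, mean_sb_interval=1.0)
        c = WellMetrics(sb_frequency=0.0, mean_sb_interval=None)
        norm, flagged = percent_of_control(m, c)
        assert "sb_frequency" in flagged and "mean_sb_interval" in flagged
        assert "sb_frequency" not in norm
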