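# Methods

This note documents the models, algorithms and numerical choices behind
`meaburst`, and what the synthetic benchmarks do and do not demonstrate.

## Signal chain

**Filtering.** Each electrode is band-passed with a Butterworth filter,
high-pass 200 Hz, low-pass 3000 Hz — the band that retains extracellular
spike energy while rejecting field-potential drift and high-frequency
noise. The single-pass order is 2 (configurable); the filter is applied
forward and backward (`scipy.signal.sosfiltfilt`), giving zero net phase
shift and an effective order of 4. Edge transients are controlled by
even (reflection) padding of at least three high-pass time constants
(3·fs/f_hp samples). Zero phase matters because spike timestamps are
compared across electrodes at millisecond resolution.

**Noise estimate.** The per-electrode noise SD is the spike-robust
median-absolute-deviation estimator σ = median(|x|)/0.6745. For a
zero-mean Gaussian background this is consistent for the SD, and because
spikes occupy well under 1% of samples at physiological rates, they
barely inflate it (unlike the sample SD, which a handful of 10-σ events
biases upward). σ is computed once per electrode over the whole
recording; a sliding-window variant would only matter for recordings
with drifting noise floors, which the simulator does not model.

**Spike detection.** A spike is registered where the filtered trace
first crosses below −5.5 σ. The timestamp is the local minimum within
the 1 ms dead-time window after the crossing (more stable against noise
than the crossing sample itself), and further crossings within the dead
time of that minimum are suppressed, so consecutive spikes are always at
least one dead time apart. Only negative-going crossings are detected —
the dominant polarity of extracellular somatic spikes. The detector is
deliberately simple enough to be specified exactly; the test suite holds
it equal to an independent per-sample exhaustive scan on random traces,
and verifies monotonicity in the threshold and invariance under positive
rescaling of the trace.

Multi-unit activity only: no spike sorting, and no artifact rejection
beyond the band-pass.

## Network analysis

**ASDR.** Spikes from all electrodes are pooled and counted in 200 ms
bins (`counts[k]` covers `k·w ≤ t−t0 < (k+1)·w`); a trailing partial bin
is dropped, from both the series and the max-ASDR statistic, so bin
counts are always comparable.

**Synchronized bursts.** The detector works on the ASDR: bins above
mean + 1.25 SD (population SD of the bin counts) seed bursts; each seed
run extends outward while neighbouring bins stay above the mean, which
places burst edges where the array-wide rate returns to baseline; bursts
whose gap is under 200 ms merge; and a burst is kept only when at least
35% of active electrodes (≥ 5 spikes/min over the recording, a common
vendor default) fire at least once inside it. The threshold is read as
an upward excursion criterion — a literal two-sided rule would classify
network silences as "bursts". The participation denominator counts
active electrodes rather than all 16 so that dead electrodes cannot veto
network events; both the fraction and the activity cutoff are
configurable. No ASDR smoothing is applied by default (a moving-average
width is exposed); burst boundaries are therefore bin-edge-quantized,
and boundary accuracy is limited to one bin width.

Because the 1.25 SD rule is scale-free, any stationary spiking process
crosses it in roughly 10% of bins; in recordings without genuine
network events it is the electrode-participation criterion that rejects
these chance excursions. This is worth knowing when analyzing wells
whose firing is spread uniformly across many electrodes at similar
rates: there, chance excursions recruit many electrodes and the
detector will report frequent short "bursts" — a property of the
algorithm itself, not of this implementation.

**Metrics.** Mean firing rate averages spikes/duration over active
electrodes (over all electrodes on request); with no includable
electrode the metric is undefined and signalled, never reported as 0.
SB frequency is bursts/min; the SB interval is the end-to-next-start
gap (onset-to-onset is easily derived from the burst table); max ASDR
is the per-recording maximum bin count. SB-derived fields are absent
(`None`) rather than zero when no (or fewer than two) bursts exist, and
percent-of-control normalization flags rather than fabricates fields
whose control value is absent or zero.

## Simulator

The generator is statistical, not biophysical — no membrane dynamics or
synaptic models. Per electrode, background spikes are homogeneous
Poisson; synchronized bursts are a renewal process (exponential gaps
plus a hard minimum) in which each electrode is recruited independently
with a participation probability and fires Poisson at an elevated rate
inside the window; spikes quantize to the 12.5 kHz sample grid, with
same-sample duplicates on one electrode collapsed (one physical event).
Voltage rendering places a biphasic template per spike — negative
half-sine lobe (40% of a 1.5 ms width) followed by a positive lobe at
30% amplitude, normalized so the sampled minimum is exactly the
configured amplitude — on white Gaussian noise; overlaps sum linearly.
Parameter sets that cannot respect the minimum burst gap are rejected as
infeasible rather than silently truncated.

Key defaults: 16 electrodes (4×4), 12.5 kHz, spike amplitude 100 µV on
10 µV noise. The amplitude-to-noise ratio of 10 is a design choice for a
healthy recording (no amplitude statistics exist to infer it from);
detection performance at lower SNR degrades and is not characterized
here. The ground-truth minimum burst gap is 0.8 s: detected burst edges
sit on 200 ms bin edges, so binning alone can shorten a true gap by up
to two bins, and 0.8 s (merge distance + two bins + margin) keeps true
bursts unambiguously separable after binning and merging — a tighter
gap would make boundary scoring ambiguous without making the scenarios
more realistic.

**Scenarios.** All fixtures are seeded and bit-for-bit reproducible.
`synchronous_network` (60 s): 0.2 Hz background, 20 bursts/min of 0.5 s
at 10 Hz per recruited electrode, participation 0.9 — a well-developed
culture with a regular SB pattern. `hyperexcitable_asynchronous` (60 s):
no bursts; two tonically active electrodes at 18 Hz over a diffuse
0.2 Hz background (mean 2.4 Hz/electrode versus the synchronous
fixture's 1.1 Hz). Concentrating the extra drive on a few electrodes is
both typical of desynchronized hyperexcitable cultures — tonic unit
firing replaces coordinated network events — and the regime in which
the participation criterion correctly rejects chance ASDR excursions
(a uniformly hyperactive well would pass them; see above). `silent`
(10 s): noise only. `single_electrode_tonic` (30 s): one electrode at
15 Hz.

**What the benchmarks show — and don't.** Passing parameter recovery on
these fixtures demonstrates that the implementation does what its
specification says under its own generative model. Real MEA recordings
add what the model omits: electrode-to-electrode amplitude and noise
heterogeneity, waveform variability and multi-unit superposition,
non-stationary rates, correlated (non-burst) activity, and movement or
media-change artifacts. Detection sensitivity and burst boundary
accuracy on real data will be correspondingly worse; the directional
contrast between scenario pairs is a property of the algorithms, not a
biological claim.

## Statistics layer

**ROUT (one-sample reduction).** For a single group the
robust-regression step collapses to the median; the robust scale is the
68.27th percentile of absolute residuals with the small-sample
correction n/(n−1); each point gets a two-sided p-value from the t
distribution on n−1 df; and a Benjamini–Hochberg step-up test at
maximum desired FDR Q = 10% flags the extreme points. With zero robust
scatter any point off the median is flagged; identical samples flag
nothing. Screening is applied per metric and per group independently.
Simulation shows the clean-Gaussian removal fraction stays near 1%,
comfortably below Q.

**ANOVA.** The omnibus one-way F test uses the standard between/within
sum-of-squares decomposition, reported with per-group mean ± SEM; the
p-value comes from the F(k−1, N−k) distribution and is test-verified
against the regularized incomplete beta function to 1e-10. Zero
within-group variance is signalled as degenerate rather than reported
as an infinite F. Post-hoc pairwise structure is intentionally out of
scope; only the omnibus test is provided.

**qPCR.** Fold change is 2^−ΔΔCt with technical replicates averaged on
the Ct (cycle) scale, normalized to a reference gene (β-actin by
convention); reciprocal comparisons multiply to exactly 1.

## Pipeline, formats, reproducibility

Voltage travels in an HDF5 container (`/voltage`, float32 µV, with
sampling-rate/layout attributes); spike trains as `electrode,time_s`
CSV with a JSON sidecar (duration, per-electrode σ, parameters) —
round-trip lossless at float64 timestamp precision. `run_pipeline`
applies one parameter set to wells grouped by condition label, rejects
mixed sampling rates, and emits per-well metrics, burst tables, a
ROUT+ANOVA comparison per metric, percent-of-control tables when a
control label is set, and a manifest echoing every tunable plus library
versions; identical config and inputs give byte-identical outputs. All
simulation randomness flows through a single integer seed per run, with
independent derived streams for spike trains and noise.

Benchmark problem sizes (60 s wells, 300 s Poisson rate-recovery wells,
20 seeds, 1000 ROUT replicates) were chosen so the whole verification
suite runs in seconds at desk scale while keeping every recovery
statistic's sampling error well inside its acceptance margin.
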