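# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinate frame and session structure

All analysis works in the tracking region-of-interest (ROI) frame: a
25 × 25 cm square, origin at the lower-left corner, 25 × 25 spatial bins
of 1 cm (half-open `[edge, edge+1)`), row-major with rows indexing y
from the bottom. The physical maze floor is a 20 × 20 cm inner square of
5 × 5 Peltier elements (4 × 4 cm each), centered in the ROI. The 2 × 2
quadrant grid splits the ROI at its midlines; quadrants are labeled
Q1..Q4 row-major from the bottom (Q1 lower-left, Q2 lower-right, Q3
upper-left, Q4 upper-right).

A session is Pre (10 min, room temperature) → Cooling (80 min, floor
cooled, warm spots heated) → Post (10 min). The standard schedule heats
the four corner elements 5 min each in a fixed 1–2–3–4 order, repeated
four times; a sleep-permissive variant uses 20-min epochs (two opposite
corners ×2, or all four corners once — both are expressible through
`corner_schedule` / `two_spot_schedule`).

## Behavior

* **Preprocessing.** Detections with likelihood < 0.5 are discarded and
  refilled by shape-preserving piecewise-cubic (pchip) interpolation on
  the original timestamps, then each coordinate passes a 7-point median
  filter. Pchip cannot overshoot between monotone neighbors, which is
  the point of using it on tracking dropouts. Refilled samples take
  likelihood = floor so one pass makes the refill stage a fixed point; a
  median filter is not strictly idempotent, so full two-pass
  idempotence holds exactly only for locally monotone signals (median
  roots) and the test suite checks exactly that.
* **Speed.** Centered finite differences, then a 0.5-s moving average.
  This estimator is not dictated by the data format and is exposed as a
  parameter; it is unbiased for uniform motion and accurate to ~0.01%
  for smooth curvature at 25 Hz. Speed is computed after median
  filtering (the alternative order is not implemented).
* **Segmentation.** Per-sample threshold at 2.5 cm/s, `>=` counting as
  movement; runs merge into intervals with boundaries at midpoints
  between samples, so movement ∪ immobility tiles the session exactly.
  Frames are assigned whole to the state of their sample (error at a
  boundary ≤ one frame, 40 ms).
* **Warm-spot metrics.** Per transition: distance-to-previous-spot
  series, departure latency (first speed ≥ 2.5 cm/s after heat-off) and
  arrival latency (first entry into the new element's 4 × 4 cm
  footprint; NaN when the animal never arrives).

## Synthetic sessions

The generator's defaults are the study conditions: 25 Hz video, 1250 Hz
LFP, the schedules above, Cooling immobility ≈ 77%, warm-spot departure
median 12.99 s and arrival median 23.45 s, ripple rate 0.136 Hz during
Cooling, 50 units with 45% place-tuned.

* **Trajectory.** A two-state semi-Markov walker. Dwell: an
  Ornstein-Uhlenbeck micro-jitter around the active spot (per-frame step
  SD 0.04 cm, speeds almost always below 2.5 cm/s). Explore: a
  reflected OU-velocity walk (stationary speed SD 5 cm/s) inside the
  walkable square. On a warm-spot switch the animal lingers a lognormal
  departure latency (median 12.99 s, σ = 0.1 log units), wanders, then
  runs to the new spot at 8 cm/s so that arrival lands around the
  23.45-s median. During dwells, exploratory bouts (hazard 1/32 Hz,
  mean 8 s) reproduce the ~77%/23% immobility/movement split of
  Cooling; Pre/Post alternate rest (mean 9 s) and move (mean 6 s)
  bouts. Only summary statistics of the real behavior are targeted; the
  dispersion of the latencies is not constrained by any reported value,
  and a modest σ was chosen so the medians are sharp at per-session
  sample sizes. Tracking glitches (2% of frames, likelihood < 0.5,
  positions displaced by ~3 cm) exercise the preprocessing stage.
* **Spikes.** Inhomogeneous Poisson with rate
  `baseline + (peak − baseline)·exp(−d²/2w²)` along the trajectory.
  Tuned units: peak 8–20 Hz, width 2–4 cm, baseline 0.1–0.5 Hz; untuned
  units: flat 0.5–3 Hz. 20% of units carry interneuron labels (labels
  only — the cell-type classifier takes waveform metrics as inputs and
  is a pure rule).
* **LFP.** Two channels of 1/f-shaped Gaussian noise (SD 20 µV).
  Ripples: 150–180 Hz Hann-windowed sinusoids, 50–100 ms, amplitude 8
  broadband-SDs, added only to the detection channel, placed uniformly
  in Cooling immobility with ≥ 0.4 s separation. Broadband 50-ms
  artifacts (9 SD, rate 0.005 Hz) hit both channels — the material for
  the noise-channel veto. There is no biophysical content: no theta, no
  sharp-wave component, no spectral nonstationarity.
* **Within-ripple participation.** Per ripple, a unit emits ≥ 1 spike
  with the participation probability of the quadrant at the ripple
  peak (defaults: 0.5 preferred / 1/6 elsewhere for tuned units, 0.25
  uniform for untuned); participating counts are zero-truncated Poisson
  (mean 1.5), spikes uniform inside the burst. For NREM-labeled ripples
  the bias contrast is attenuated ×0.5 toward uniform — place coding
  persists into sleep, weakened. The count distribution is a modeling
  choice (no reported distribution constrains it) and is exposed as a
  parameter.
* **Brain states.** All WAKE under the 5-min schedule. Under ≥ 20-min
  epochs, NREM fills the second half of each epoch (sleep after
  prolonged dwells); bouts partition the session.

What passing tests therefore show: the *statistics* are implemented
correctly and recover generating parameters under idealized noise. They
do not show robustness to real-LFP nonstationarity, theta contamination,
spike-sorting errors, or behavioral idiosyncrasies.

## Ripple detection

Third-order Chebyshev type-I band-pass (1 dB passband ripple), applied
forward-backward for zero phase — event boundaries are not skewed by
filter delay. The squared trace is z-scored and then smoothed with a
12.8-ms moving average (16 samples at 1250 Hz); excursions above 2 SD
containing a ≥ 5 SD peak become events (this implicitly merges
overlapping threshold crossings), then the 20–200 ms duration limits
apply. Normalizing before smoothing references the SD of the unsmoothed
squared trace; the alternative (smooth, then z-score) is available via
`smooth_before_z=True` but makes isolated single-sample power spikes in
background noise detectable after smearing, raising the false-positive
rate on pure noise by ~50×. Amplitude is the peak absolute value of the
band-passed trace in the event (µV); peak frequency is the argmax of a
zero-padded periodogram (1 Hz resolution) restricted to the band, with a
low-confidence flag below three oscillation cycles. An alternative mean
cycle-frequency estimator was considered and not implemented; the
periodogram argmax is the package's single estimator.

## Spatial maps and place cells

Rate maps divide movement spike-count maps by movement occupancy.
"2-bin smoothing" is implemented as a Gaussian kernel, σ = 2 bins
truncated at 4σ, with occupancy-weighted renormalization
(`smooth(counts)/smooth(occupancy)`): constants are preserved, unvisited
bins neither receive nor donate mass, and they stay masked (never
zero-filled) in correlations. A 2 × 2 boxcar is available behind a flag.
SI is computed on *unsmoothed* rates — smoothing inflates SI in a
bin-count-dependent way. The block shuffle concatenates movement
frames, cuts 5-s blocks, and circularly rotates block order by a random
offset ≥ 1 block (guaranteeing non-identity permutations while
preserving within-block autocorrelation); it requires ≥ 20 blocks.
Peak rate for the place-cell rule is taken from the unsmoothed map.

## STS and its null

Each event's 300-ms window is trimmed at the midpoint between adjacent
peaks when windows overlap, so no time is double-counted and each
window's time belongs wholly to the event's peak-time quadrant. The
null permutes the quadrant-label multiset across events — per-quadrant
event counts are preserved exactly — and recomputes rates from the
fixed per-event spike counts and window durations, which is
algebraically identical to relabeling events but avoids re-intersecting
intervals per shuffle. p uses the add-one convention (never zero).
1000 shuffles by default, a resolution choice (the reported place-cell
shuffle count, 100, is kept for SI). Argmax ties break to the lowest
quadrant index and are flagged.

## Decoder

Log-space evaluation of the Poisson population posterior with C = 1,
τ = 0.3 s, and a rate floor ε = 0.01 Hz applied to the templates inside
the likelihood (both the log term and the exponential-sum term — the
likelihood is that of a Poisson with rate max(f, ε)); stored templates
keep exact zeros. The printed form of the exponent uses the window
length τ. Cross-validation partitions events randomly (seeded) into
100 near-equal folds; per-event windows and spike counts are computed
once over all events, fold templates aggregate training events only,
and a fold whose training set leaves a quadrant with zero window time
is skipped and tallied. Session accuracy is the mean of fold
accuracies. Chance level has no canonical definition here; the default
is the mean cross-validated accuracy over label permutations, with the
closed form Σ_x q_x² behind a flag.

## Population vectors

Rate ratios use the *sum* of quadrant rates as denominator for every
condition (ratios ∈ [0, 1] on a shared scale). A mean-denominator
convention differs by ×4, which Pearson correlation ignores, so results
are identical. Unit exclusion is listwise but scoped to the conditions
actually being compared. Both pooled (unit × quadrant) correlations and
quadrant-wise vector correlations are computed and labeled — the two
summarizations answer slightly different questions and the tables keep
them apart.

## Problem sizes

The default test suite runs short sessions (1 min Pre/Post, 20 min
Cooling with 75-s epochs) for structural checks and full-length
sessions for the recovery closures (place cells: 50 units × 3 seeds;
population vectors: 100 units × 10 seeds; decoder: 30 units, 500
events). The acceptance script uses full-length sessions with 50 and
100 units. These sizes give stable statistics at per-session scale; all
of them are parameters, not constants.

## Known limitations

* The generator's trajectory has no thigmotaxis, no room-temperature
  home-base behavior, and no bimodal dwell durations; only the summary
  fractions and latencies are matched.
* The LFP model cannot probe detector behavior under theta/gamma
  contamination or electrode drift.
* No replay-sequence structure exists inside ripples — participation
  bias only — so sequence-level analyses are out of scope by design.
* Place-field definition is purely threshold-based (peak, SI, shuffle
  z); no field-contiguity criterion is applied.
* NREM labeling is schedule-driven in the generator; real state scoring
  is an upstream input, not part of this package.
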