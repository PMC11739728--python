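# Methods

This note documents the models, conventions and parameter choices behind
`cannasense`, the assumptions they rest on, and what the test suite does
and does not establish.

## Problem setting

The pipeline targets three-class detection of self-reported cannabis
intoxication — not-intoxicated (N, rating 0), low (L, 1–3), and
moderate-intensive (MI, 4–10) — from passively sensed smartphone and
wearable streams, with experience-sampling (ESM) self-reports as ground
truth. Sensor statistics are computed on 5-minute windows: short enough
to track the rapid physiological onset of smoked/vaped cannabis (heart
rate rises within minutes), long enough to hold a usable number of
samples per stream.

## Windowing and time

All timestamps are POSIX epoch seconds (UTC). Each participant has a
fixed UTC offset; local clock quantities (hour of day, day of week,
calendar day) are derived by shifting the epoch, which sidesteps DST
ambiguity entirely. Windows are half-open `[t, t+300)` intervals aligned
to clock epochs (…:00, :05, :10), so window identity is reproducible
across runs and a sample on a boundary belongs to the window that starts
there. Windows tile each participant's observed span with no gaps or
overlaps; the partition property is asserted by tests.

The study never states whether its windows were aligned to clock epochs
or to episode starts; epoch alignment was chosen because it makes window
identity a pure function of the timestamp.

## Labeling rules

* Report filter order: missing rating → exact duplicate (same
  participant, start, end, rating; first kept) → missing start/end or
  duration outside (0, 180] minutes. The order changes only the audit
  attribution, not the surviving set; it is fixed so audits are
  reproducible. "Duplicate" is exact field equality — nothing softer is
  defensible without the raw data.
* Episodes carry a 30-minute pre-start buffer (reporting latency: pilot
  observations put self-report delay at 5–15 minutes) and a 3-hour
  post-end buffer (residual effects). Buffered windows are EXCLUDED even
  for rating-0 episodes; windows *inside* a rating-0 episode are labeled
  N.
* Any overlap with the episode interval labels a window (episodes as
  short as one window would otherwise vanish). A window overlapping two
  episodes of different classes is EXCLUDED with an audit note — the
  source accounting is silent on this case.
* N windows are sampled only from anchor days: local days holding a
  fixed-time survey answered "no use since last report" with last use
  strictly more than 5 hours prior, and containing no episode. Sampling
  is seeded and capped per day (default 24 windows) to keep the N class
  dominant but the feature-extraction cost bounded; the real study's N
  class is relatively larger, which only strengthens the imbalance that
  oversampling corrects.
* The three sensor variants are evaluated on the common window set
  (windows with both smartphone samples and valid wearable HR), so they
  differ only in feature columns.

Known source-data ambiguities we deliberately carry as published and do
not resolve: a stream-sample total whose printed parts sum 18 higher
than the printed total, and a participant-count chain that is internally
inconsistent; neither affects the package's own arithmetic, which is
tested end to end.

## Feature definitions and defaults

* Radius of gyration: RMS great-circle (haversine) distance of a
  window's fixes from their centroid, meters. Clustering is sequential
  seed-based grouping with a 30 m threshold (no published value exists;
  30 m separates rooms/buildings from genuine relocation at consumer GPS
  accuracy). `time_at_cluster` is the dwell span of the longest-dwell
  cluster.
* Weighted stationary SD (WTSD): dwell-time-weighted SD of latitude
  (resp. longitude) over fixes whose hop speed is below 0.5 m/s. The
  weighting was named but never defined in the source literature; dwell
  weighting is the natural reading.
* Phone angle: tilt from vertical, `arccos(|a_z|/‖a‖)`, from the
  accelerometer gravity vector.
* Audio: frames carry an inferred class and an amplitude; energy is
  amplitude². Class cutpoints are configurable (defaults: silence < 3,
  noise < 5, voice < 6.5, else unknown) because the upstream inference
  plug-in's thresholds are unpublished. The Wi-Fi "most contacted access
  point" is encoded as a stable CRC32 hash bucket (16 buckets) of the
  window's modal AP id.
* HR: readings strictly below 40 bpm are removed as artifacts before any
  statistic (40.0 is retained). Skewness is the moment coefficient
  g₁ = m₃/m₂^{3/2}; kurtosis is excess (normal → 0) — "peakedness" alone
  does not pin the convention, so it is fixed and declared for
  reproducibility. Both need ≥3 samples and nonzero spread.
* Resting HR: mean valid HR over a maximal zero-step run strictly longer
  than 5 minutes overlapping the window (largest overlap wins). The mean
  was chosen as the run statistic; the alternative (median) was not
  distinguishable from available descriptions. A gap in the per-minute
  record breaks a run, since activity during unobserved minutes is
  unknown.
* Prior-night sleep: a window on local day d receives the most recent
  sleep record ending by noon of day d; the noon boundary attributes
  post-midnight onsets (observed up to ~4 AM) to the night they belong
  to. Sleep start time is encoded as hours after noon so one night's
  onsets are monotone (23:00 → 11, 03:30 → 15.5). Duration is time in
  bed, minutes awake reported separately.
* Missing-stream windows carry NaN, never zero — zeros would fabricate
  silence or stillness. Imputation (training-set median) happens only in
  the modeling stage.

The feature dictionary order is the documented column order; it matters
because correlation pruning keeps the first-listed member of an
offending pair. `hr_min` deliberately leads its stat family so the
minimum-HR marker survives pruning of the mutually correlated HR stats.

## Synthetic cohort

The generator's defaults are the study conditions the pipeline targets:
30-day cohorts; ~0.6 evening-peaked use episodes per participant-day
(start-hour mode 22:00–23:00, durations ≤ 3 h weighted toward short
sessions); ratings drawn from the observed 0–10 event distribution
(mean 3.63, SD 2.72 over 129 events); self-reports delayed 5–15 minutes
after episode start, with small rates of missing ratings (1%), exact
duplicates (2%), missing (2%) or corrupted-past-3 h (1%) end times, and
85% fixed-survey compliance.

Streams: heart rate is a diurnal sinusoid around 70 bpm (amplitude
3.5 bpm, acrophase 17:00) minus a small sleep dip, plus an
activity-coupled term and white noise (SD 2.5 bpm); locations are three
anchor places per participant with 15 m Gaussian jitter and occasional
trips; ambient noise energy has a diurnal mean with SD 5; sleep onsets
are ~23:18 ± 1 h. None of these baselines is published — they are
placeholder distributions tuned for test power, not physiological
fidelity.

Injected effects during truth-MI minutes (defaults): +10 bpm HR,
mobility displacement ×0.5, noise-energy SD ×1.5, and prior-night sleep
drawn from 8–11 h (baseline 6–8 h) on days containing an MI episode.
Effect-recovery tests stratify the raw streams by the hidden truth trace
and match on clock hour (and wakefulness, for HR), because episodes
concentrate in the evening and an unmatched contrast would confound the
injected delta with the diurnal structure.

What the generator does **not** model: between-participant physiological
heterogeneity, tolerance effects, polysubstance confounds, realistic GPS
multipath error, device clock drift, or correlated nonrandom
missingness. Passing recovery and classification tests therefore shows
the pipeline detects the stated effect structure at the stated sizes —
not that real-world detection reaches these scores. Real-data
performance is a property of the original study cohort, which is not
redistributable; the package reproduces the metric identities of its
published confusion matrices exactly, and the qualitative structure
(combined sensors beat single sources; injected markers top the MI
attribution ranking) stochastically.

## Modeling choices

* Split: stratified 80/20, seeded. Stratification is not guaranteed by
  the source description; it was chosen to keep the rare L class present
  in the test set at desk scale.
* Pruning threshold 0.9 (strict: |r| = 0.9 survives), impurity-importance
  threshold 0.005 on a 300-tree auxiliary random forest; pruning runs
  before selection on the identical pool, following the pipeline's
  left-to-right description.
* Oversampling: synthetic minority rows are convex combinations
  x_i + u(x_nn − x_i) of k ≤ 5 same-class nearest neighbors, applied
  inside each training fold and to the final training set only — never
  to validation or test rows (asserted by hashing).
* Hyperparameter search space: trees 50–300 (log), depth 2–8, learning
  rate 0.02–0.3 (log), subsample 0.6–1, column subsample 0.5–1, minimum
  child weight 1–16 (log). The search is a Matérn-5/2 GP surrogate with
  expected-improvement acquisition over the unit cube (first third of
  the budget random), maximizing mean 10-fold stratified CV macro-F1;
  ties and the final model refit use the seeded configuration, so a
  fixed seed reproduces the chosen hyperparameters exactly.
* CV optimizes macro-F1, the same unweighted-mean convention the
  evaluation module uses; that convention is pinned because it exactly
  reproduces every published summary metric from the published
  confusion matrices at 2-decimal rounding.
* Degenerate inputs: single-class training data raises; classes never
  predicted yield NaN precision, excluded from macros with an audit
  note; fold counts shrink to the smallest class when 10 folds are
  infeasible.

## Attribution

Attributions are exact Tree SHAP values in class-margin (log-odds)
space, from the boosting library's polynomial-time path algorithm; the
MI-vs-rest view is the MI class's attribution slice, not a refit binary
model. Local accuracy (base + Σφ = margin) is asserted at rtol 1e-4 /
atol 1e-5 — the contribution computation runs in single precision, so a
tighter tolerance is not attainable. Summary rankings use mean
|attribution| per feature, pooled over classes or MI-only; both views
are exported because published summary plots do not state which pooling
their left-hand panels use.

## Problem sizes

Default test and acceptance runs use cohorts of 4–20 participants over
10–30 days, a 24-window/day cap on N sampling, 2–4 search trials, and
ten seeds for ranking-stability checks. These sizes give the stochastic
assertions comfortable margins (MI recall ≈ 0.99 against a permutation
baseline ≈ 0.18; 4/4 injected features in the top-10 MI ranking in the
probed seeds) while keeping a full run on one CPU in minutes.

## Known limitations

* The sequential location clustering is order-dependent by design (it
  mirrors streaming use) and is not a global optimum clustering.
* The Wi-Fi hash-bucket encoding makes the modal AP usable by trees but
  bucket collisions are possible across participants.
* AUC aggregation is macro one-vs-rest; micro aggregation cannot be
  distinguished from available summary values and is not offered.
* The generator emits inferred audio classes directly (as the upstream
  sensing framework does); there is no raw-audio DSP path.
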