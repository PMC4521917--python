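# Methods

This note documents the models, conventions and numerical choices behind
`swaysom`, in the order the pipeline runs.

## Synthetic sway cohorts

The generator emulates markerless skeleton capture of a lateral
weight-shifting balance exercise.  It is a *statistical* stand-in for real
recordings: it reproduces the data geometry (15 segments, 3-D, irregular
~30 Hz), the cohort layout, and the group/condition structure the analysis
is meant to detect — not validated balance physiology.

**Kinematic model.**  The lower back follows a base oscillator
x(t) = −A(t)·cos(2π·φ(t)), where the phase φ advances through successive
cycles whose periods are drawn per cycle as T·(1 + ε), ε ~ N(0, v²), and
the amplitude knot of each cycle is A·(1 + δ), δ ~ N(0, v²), linearly
interpolated between cycle midpoints (v is the subject's
`variability_level`).  A cycle starts at the outermost-left position, so
cycle boundaries sit at integer phase.  Every other landmark is an
amplitude-scaled, phase-lagged copy of this oscillator (head/neck/
shoulders lead the pelvis by 0.03 cycles and overshoot it; knees move
little, feet barely), with vertical displacement following an
inverted-pendulum coupling y = y₀ − L·(1 − cos(d/L)) for lateral
displacement d and pendulum length L equal to stature.  The leg-lift
condition adds a lean-gated vertical lift of the contralateral knee/foot.
Gaussian sensor noise (SD 2 mm) is added to every coordinate and
timestamps are jittered uniformly within ±5 ms of the nominal 1/30 s grid.
Axes: x medio-lateral (positive right), y vertical (up), z sagittal;
metres; right-handed.  Each trial generates `n_cycles + 2` oscillations so
that discarding the first still leaves the requested number.

**Cohort structure.**  Defaults: 20 young + 20 old subjects, five task
conditions (neutral; increased game speed; maximum sway frequency;
leg lift; maximum sway amplitude), two trials each — 400 trials.  Subject
parameters are drawn per group: amplitude 0.10 ± 0.01 m (half-excursion of
the lower back), frequency 0.45 ± 0.04 Hz, variability 0.05 ± 0.008,
stature scale 1.00 ± 0.04.  The condition multipliers (amplitude ×1.6 for
maximum amplitude, frequency ×1.8 for maximum frequency, mild changes
elsewhere) were fixed once as plausible task responses.

**Old archetype.**  Group effects are confined to the two complex
conditions (maximum frequency, maximum amplitude): there old subjects
reach only 0.8× the amplitude and 0.8× the frequency of their base values
and show 1.5× the cycle-to-cycle variability.  An earlier variant applied
the amplitude reduction in every condition; that couples with the constant
sensor noise — amplitude equalization amplifies a quieter signal's noise
more — and produces spurious TTvar group differences in the *neutral*
condition.  Restricting all three factors to the complex conditions keeps
the neutral condition signal-free by construction, which is the structure
the group-comparison analysis assumes.

**Corrupted trials.**  To exercise the discard rule, 8 young and 14 old
trials (by default) are generated with only 5 sway cycles; preprocessing
then drops exactly those 22, retaining 378 of 400.

**What passing tests do not show.**  The generator's cycles are smooth,
stationary and unimodal; real sway contains drift, pauses, asymmetries,
marker-tracking glitches and postural strategies (hip vs ankle) that the
planar chain cannot produce.  Tests passing on this cohort validate the
pipeline's mechanics and statistical behaviour, not clinical validity.

## Preprocessing

- Resampling: cubic splines (one spline per coordinate) evaluated on a
  uniform grid spanning the recorded interval — no extrapolation.  Inputs
  with fewer than 4 frames or non-monotone timestamps are rejected.
- Frontal reduction: label-driven selection of the nine landmarks and the
  (x, y) axes; hands, elbows, feet and the sagittal axis are dropped.
- Cycle detection: local minima of the mean of the two shoulder ML
  signals, with prominence at least 25% of the signal's interquartile
  range (the landmark is prescribed; the detector is ours).  The
  prominence floor makes the detector ignore sensor noise while keeping
  every genuine turning point at the default noise level.
- Cycle selection: drop the first detected cycle, keep the next ten;
  fewer than ten remaining ⇒ the trial is flagged discarded (an outcome,
  not an exception).
- Sway amplitude: mean over the selected cycles of the per-cycle
  peak-to-peak ML excursion of the lower back.  "Distance covered" could
  also be read as path length; peak-to-peak excursion is the quantity the
  maximum-amplitude task manipulates, so that reading is used.
- Sway frequency: argmax (excluding the zero bin) of a periodogram of the
  linearly detrended, Hann-windowed lower-back ML signal over the whole
  trial.  Estimated per trial, not per cycle, for spectral resolution.
- Time normalization: each cycle's 18 signals are linearly interpolated at
  phases 0, 1/30, …, 29/30 of the cycle (left-closed, right-open, so
  consecutive cycles do not duplicate the boundary frame).  All 18 signals
  share the cycle's time base, preserving inter-segment phase lags.
  Indices are 0-based internally, 1-based in exported tables.

## Amplitude-equalizing normalization

Centering removes each trial's mean posture; the rescale factors
fᵢₖ = m̄ₖ/mᵢₖ equalize each coordinate's mean absolute excursion across
trials while preserving the amplitude ratios *between* coordinates.  The
per-trial amplitude is mᵢₖ = meanⱼ |cᵢⱼₖ|: a per-coordinate quantity, which
is what makes an I × K table of scale factors well defined (a whole-vector
norm variant, which equalizes overall posture-vector magnitude instead, is
available as `mode="vector_norm"` but is not the default).  Zero-amplitude
coordinates raise an error naming the trial and coordinate — silent
division by zero is never allowed.  The model (grand means + per-trial
tables) is JSON-persistable; `normalize_with_grand_means` applies frozen
grand means to held-out data and is exactly invariant under rescaling a
trial's raw coordinates.  After fitting on the whole cohort the defining
identity meanⱼ|ψᵢⱼₖ| = m̄ₖ holds to ~1e-15 relative and is asserted at
1e-9.

## Self-organizing map

Sequential (online) Kohonen training.  Geometry: a rows × cols lattice
(default 25 × 25 = 625 nodes), node coordinates (x, y) = (column, row),
0-based; BMU ties resolve to the smallest row-major index.  Weights are
initialized uniformly within the per-coordinate data range.  One iteration
presents every training vector once in a freshly shuffled (seeded) order;
the update is w ← w + η·exp(−d²/2σ²)·(v − w) with d the Euclidean lattice
distance to the BMU.  Schedules: σ decays linearly from max(rows, cols)/4
to 1 and η from 0.5 to 0.01 over the configured epochs.  The classical
toolbox defaults these schedules imitate are not uniquely defined, so all
four endpoints are exposed in `TrainingSchedule`; the qualitative
behaviour (quantization-error decrease, topology preservation) is what the
tests pin down, not specific weight values.  Quantization error (mean
input-to-BMU distance) is recorded per epoch.

Desk-scale defaults: the library default remains 25 × 25 / 1000 epochs,
but every entry point accepts a row subsample and epoch count.  The
acceptance script trains the posture map on 8 000 of the 113 400 input
rows for 30 epochs and the 600-d trajectory map for 60 epochs — enough for
a stable lattice organization at a ~30 s total runtime; these sizes are
reported alongside the results.

## Trajectory variability

TTvar: frame j (cycle c, phase b) receives the mean Euclidean *lattice*
distance between cycle c's BMU at phase b and the other nine cycles' BMUs
at phase b; TTvar is the sum of the 300 entries.  Distances are taken in
2-D lattice coordinates (trajectories live on the map; the weight-space
variant is available for comparison but is not the default).  This
per-frame construction is, up to a fixed constant, the sum over the 30
phases of the mean pairwise distance over the 45 cycle pairs — so group
comparisons and monotonicity results do not depend on the choice of
constant.  TTvar ≥ 0 with equality iff all ten cycles coincide, and the
phase-level aggregate is invariant under relabeling the cycles.

Phase split: the left turning point anchors at phase 1 (cycles start at
the outermost-left position) and the right turn at phase 16 (mid-cycle);
the endpoint windows are the 7 phases centred on each anchor, wrapping at
the cycle boundary — 14 endpoint and 16 traveling phases.  Per-phase
variability ellipses use the SEM (not SD) of the ten x- and y-coordinates
as horizontal/vertical radii and area π·h·v.

Mann-Whitney U: midrank tie handling; exact two-sided p by full
enumeration of group assignments for combined n ≤ 12, otherwise a normal
approximation with tie and continuity corrections.  The U statistic is
reported for the first sample (old, in the group comparison).

## Classification

Trajectory vectors concatenate the 300 x- then 300 y-coordinates of a
trial's BMUs (600 values).  By default only trials from the two complex
conditions enter the second SOM (600-d weights, same lattice geometry).
kNN runs on the trials' 2-D BMU coordinates on that second map (a flag
allows classifying the raw 600-d vectors instead); k = 5, Euclidean
distance, majority vote with ties broken by the nearest neighbour.
Evaluation: 100 stratified random 70/30 splits (stratification avoids
degenerate single-class training sets at small n); per-run accuracies are
retained alongside the mean.  On the default synthetic cohort the mean
accuracy lands modestly above chance (~51–56% across seeds): after
amplitude equalization and time normalization the residual group signal is
cycle-to-cycle scatter, which the trajectory's mean shape encodes only
weakly — the expected regime for this feature set, and the reason the
TTvar statistic, not the classifier, is the primary group contrast.

## Numerical and degenerate-input policy

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed ⇒ identical
  datasets, trained maps and reports.
- Preprocessing errors are typed: malformed input (too few frames,
  non-monotone time, missing segments), no-cycles, configuration errors.
  Trial discard is a reported outcome, never an exception.
- Constant (zero-amplitude) coordinates are detected with a relative
  threshold (1e-12 of the data magnitude) since centering a constant
  column leaves rounding residue rather than exact zeros.
- The normalization post-condition is verified at apply time (1e-9
  relative) and can be disabled for held-out data normalized against
  frozen grand means.

## Known limitations

- The generator does not emulate Kinect depth-image artifacts, occlusion,
  or skeleton-fitting failures; "corruption" is modelled only as
  too-few-cycles trials.
- TTvar magnitudes depend on lattice size and on how much of the map the
  cohort occupies; only within-analysis comparisons are meaningful.
- The SOM is trained on a subsample at desk scale; node-level map layouts
  vary between seeds even though the group-level statistics are stable.
- RM-ANOVA-style factorial analyses of the phase/condition structure are
  out of scope; standard statistics packages can consume the exported
  per-phase tables directly.
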