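# Methods

This note documents the models, processing conventions and design choices
behind `tunatag`, and what the synthetic-data tests do and do not
demonstrate about real tag records.

## Record classes and timing conventions

Two record classes are handled: high-rate archival accelerometer tags
(tri-axial acceleration at 20 or 30 Hz, depth/temperature at 1 Hz) and
low-rate pop-up archival tags (everything at 0.2 Hz).  30 Hz records are
decimated to 20 Hz by linear interpolation so all high-rate records share
one grid; the lateral tailbeat signal is physically lost below 5 Hz
sampling, so wavelet tailbeat metrics are refused for low-rate records and
the pipeline marks them "not computable".

All timestamps are UTC (no time zone is stated for the study region's day
boundaries; UTC is within ~20 min of local solar time there).  "Hour h
post-release" is the release-aligned interval [release + (h−1)·3600 s,
release + h·3600 s), 1-based; "day d post-release" is the analogous 86400-s
interval.  The 24-h immediate-response analysis uses release-aligned hours;
the 30-day diel analyses bin by calendar clock hour.  Missing samples are
masked, never interpolated.

## Acceleration processing

Static (postural) acceleration is the centered running mean of each axis
over 2 s; dynamic acceleration is the exact residual, so raw = static +
dynamic holds per sample.  All running means use shrinking (partial)
windows at the edges rather than reflection or zero padding: the release
instant is the most heavily analysed moment in the record and padding would
fabricate data there.  At 0.2 Hz a 2-s window holds less than one sample,
so low-rate records use a 25-s (5-sample) window; the original processing
is silent on low-rate static separation, and the choice is exposed in
`PipelineConfig.static_window_lowres_s`.

VeDBA is the per-sample Euclidean norm of the dynamic triplet, optionally
smoothed with a 10-s running mean.  The 10-s smoothing is applied *after*
down-sampling high-rate records to 0.2 Hz (the ordering is ambiguous in the
source description).  Down-sampling is nearest-sample decimation —
an instantaneous reading every 5 s, which is how the low-rate tag itself
samples — not block averaging.

Tag-frame to fish-frame calibration composes intrinsic z-y-x rotations
(yaw about heave, pitch about sway, roll about surge, right-handed, x =
surge, y = sway, z = heave); the axis convention is documented here because
vendor conventions differ.  Rotation preserves per-sample norms, so VeDBA
is invariant to calibration applied before the split in the degenerate
single-sample-window case.

### Plateau (stabilisation) detection

"Stabilised once mean values had plateaued" names a shape, not an
algorithm.  The detector fits y(h) = A·e^(−kh) + C to the 24 release-aligned
hourly means by least squares and reports the smallest integer hour with
A·e^(−kh) ≤ 0.05·A, i.e. ceil(ln 20 / k).  The 5 % criterion is exposed in
config (`plateau_frac`).  If the fit fails or decays the wrong way
(A ≤ 0 or k ≤ 0), the fallback is the first hour from which all later means
stay within ±10 % of the late (hours 18–24) mean.  A constant series
plateaus at hour 1.

## Tailbeat wavelet metrics

The scalogram is a complex Morlet CWT (centre frequency ω₀ = 6, the
standard choice; PyWavelets wavelet `cmor2.0-0.9549`) over 32 log-spaced
periods between 0.125 s and 2 s, so DSF is confined to 0.5–8 Hz.
Magnitudes are amplitude-calibrated per scale against reference unit
sinusoids, making the ridge magnitude of a pure sinusoid equal its
amplitude within 2 %.  Long records are transformed in overlapping blocks
(8-s pads, the 4× maximum analysed period) to bound memory; block and
single-pass outputs agree to float32 precision.

Per 1-s half-open release-aligned interval, DSF is the period of maximal
mean magnitude refined by a three-point parabolic fit over log-period (so
frequencies are not quantised to the scale grid; the refinement keeps the
recovered frequency within ~0.02 Hz of truth against the ~0.05 Hz grid
spacing near 1.2 Hz), TBA is the calibrated ridge magnitude, and TBP =
1/DSF.  Intervals whose ridge falls below a 0.01 g noise floor report no
DSF.  TBA is a re-implementation defined by this calibration contract — the
original desktop tool's peak-tracing feature has no published formula — not
a port.  Size normalisation divides TBA, DSF and TBP by curved fork length;
dividing a frequency by a length is dimensionally odd but is the published
correction, and is applied as printed.

## Events

The first dive is the first maximal run of depth > 10 m lasting ≥ 20 s.
Depth is optionally temperature-corrected (depth − c·(T − T_ref); the
correction is named but not specified in the source, so c defaults to 0 and
is calibrated per tag when metadata provides it) and smoothed to a 10-s
running mean.  At 0.2 Hz that smoothing systematically extends a sharp-edged
dive by about one sample per edge; detector-level tests therefore assert
duration on the unsmoothed trace, and pipeline durations carry a ≤ 10-s
smoothing bias.

Fast starts are maximal runs of VeDBA *strictly above* the deployment-wide
99th percentile (linear-interpolation quantile); the strict inequality
makes the constant-series case well defined (no events).  For high-rate
records detection runs on raw VeDBA; for low-rate records on the 10-s
smoothed series used elsewhere (the source does not state which series the
percentile was computed on).  Events spanning midnight are split so daily
percent-time accounts every second once.  A day with < 1 % of observed time
in fast starts is inactive; weeks are release-aligned 7-day blocks.

## Diel classification and the similarity test

Day/night is a half-open [sunrise, sunset) partition.  Solar times come
from the NOAA solar-position algorithm (zenith 90.833°) when positions are
available, or fixed 06:00/18:00 UTC boundaries otherwise (the simulator's
exact ground truth).  Lunar phase is the synodic fraction from a reference
new moon, binned at 45°/135°/225°/315°; daily metrics are compared across
the four phases with Kruskal–Wallis tests.

Diel classification screens both groups with Shapiro–Wilk at 0.05, then
applies a Welch t-test (both normal) or Wilcoxon rank-sum; diurnal
(nocturnal) requires significance at α = 0.05 plus the larger day (night)
mean.  The return of diel behaviour is the earliest *diurnal* day opening a
7-day window containing ≥ 3 diurnal days — anchoring at a diurnal day
reports the day the pattern resumed rather than a preceding non-diurnal
day.

The similarity statistic: per day, a 24-vector of clock-hour means; per
ordered pair of distinct days in a 30-day block, the zero-lag Pearson
correlation over common non-missing hours (pairs with < 3 common hours or a
constant profile are dropped, not imputed); per day, the median of its 29
pairwise correlations.  Days are ranked 1 (most dissimilar) to 30 with ties
broken by calendar order.  The null shuffles the rank vector 10,000 times
without replacement; each day position's threshold is the inverted-CDF 5th
percentile of its resampled ranks, and a day is flagged when its observed
rank is ≤ that threshold.  With 30 distinct values the threshold is 2 for
any seed — P(rank ≤ 1) = 3.3 % < 5 % ≤ P(rank ≤ 2) = 6.7 % — so exactly the
two lowest-ranked days are flagged, which is why the flagging operates on
ranks with an inclusive comparison (both switchable in config): it is the
only reading that yields a deterministic two-day flag set per block.

The altered-week rule: the first week is altered when at least one of days
1–7 is flagged *and* the mean rank of days 1–7 lies in the lower half of
the 1–30 scale.  "Lower half" is implemented as ≤ 15 (inclusive) by
default, with the strict < 15 reading available via
`PipelineConfig.rank_mean_inclusive`.  Under an exchangeable null the
altered probability has a closed combinatorial form — the probability that
a uniform random 7-subset of {1..30} contains 1 or 2 and sums to ≤ 105 —
which the calibration test computes by exact subset-count dynamic
programming and matches against 10,000 Monte-Carlo pipeline trials.

## Movement

Distances are haversine great circles on a 6371-km sphere (no formula is
named in the source; this is the conventional choice).  Turning angles are
signed changes of initial bearing between consecutive daily steps, wrapped
to (−π, π], defined from the third day on.  The straightness index is net
displacement over cumulative path length, clamped to [0, 1].

The movement model is a 2-state hidden Markov model: per-state gamma step
lengths (parameterised by mean/sd), per-state von Mises turning angles, a
2×2 transition matrix with its stationary distribution as the initial law
(the source is silent; stationarity is the natural choice for a chain
observed mid-flight).  Days with undefined angles contribute the step
density only; no zero-step mass component is included.  The likelihood is
maximised directly (L-BFGS on log/logit-transformed parameters) over the
scaled forward recursion, from 25 random restarts (default) initialised
around step quantiles; the fitted states are relabelled so "directed" is
the larger step mean.  Decoding is Viterbi with deterministic first-index
tie-breaks; model checking uses one-step-ahead probability-integral-
transform pseudo-residuals of the steps, uniform under a correct model.
Depth-by-state comparisons fit a linear mixed model of log mean depth on
day/night × state with a per-fish random intercept (statsmodels MixedLM).

## The synthetic generator

The generator's defaults are the study conditions themselves: dominant
stroke frequency 1.18 Hz at tailbeat amplitude 0.06 g; a first hour 2.4×
more active than hours 2–24; stabilisation over 6 h; an 11-day subdued
phase with no diel structure; day/night VeDBA of 0.30/0.18 g afterwards; a
first dive of 4.05 min per fight-minute minus 8.35 min (clamped ≥ 8 min) to
34 m; fast starts as Poisson raised-cosine bursts peaking at 4× the local
tailbeat amplitude (400/day active, 20/day subdued — ≈1.6 % vs ≈0.1 % of
the day, straddling the 1 % inactivity cutoff); tracks alternating directed
(73 ± 14.7 km/day, von Mises κ = 10) and localised (22.8 ± 22.8 km/day,
κ = 0.5) states with 0.9 self-transition probabilities.

Calibration conventions, all fixed analytically at design time:

- `burst_decay_hours` is the time for the excess activity to decay to 5 %
  of its initial value (τ = decay_hours/ln 20), mirroring the plateau
  detector's 5 % criterion; hourly means of an exponential are again
  exponential in the hour index, so the detector sees the configured rate.
- the initial excess solves mean(hour 1)/mean(hours 2–24) =
  `burst_multiplier` in closed form, because the published burst figure is
  exactly that measured ratio.
- activity levels are mean-VeDBA targets: the oscillator amplitude inverts
  a quadrature-computed map a ↦ E‖(n₁, a·sinθ + n₂, n₃)‖ (noise floor
  included) and pre-compensates the running-mean attenuation of the static
  split, evaluated by the Dirichlet-kernel gain at the oscillator's *alias*
  frequency — at 0.2 Hz the 1.18 Hz tailbeat aliases to 0.02 Hz, where a
  5-sample mean removes ~65 % of the amplitude.  The compensation is
  floored when the oscillator sits on a multiple of the sampling rate
  (its samples are then constant and indistinguishable from posture).
- depth noise is AR(1) with a 30-s correlation time; fast-start shapes are
  synthetic stand-ins (no waveform-level description of real fast starts
  exists); day/night ground truth uses fixed 06:00/18:00 UTC boundaries.

What passing recovery tests show: the analysis chain is self-consistent —
each configured effect size survives the full static-split/wavelet/
binning/ranking path within stated tolerance.  What they do not show:
robustness to tag wobble (low-rate tags read ~1.3× higher VeDBA than
double-anchored high-rate tags in the field, and no wobble physics is
simulated), to light-based geolocation error, to gaps and sensor drift, or
to behaviour outside the modelled repertoire.

## Problem sizes and numerics

Acceptance-grade checks use 20 seeds of 25-h 20 Hz records for signal
recovery (with wavelet metrics evaluated on 10-min plateau windows),
500-day tracks with 6–8 optimizer restarts for HMM recovery, 10,000
permutations for null thresholds and 10,000 Monte-Carlo blocks for the
altered-week calibration; these sizes give Monte-Carlo errors comfortably
inside the asserted tolerances.  The forward recursion is validated against
brute-force path enumeration (≤ 10 steps) to 1e-8; quantiles use numpy's
linear-interpolation convention except the permutation threshold, which
uses the inverted CDF (the empirical quantile the flagging rule requires).

## Known limitations

- The altered-week mean-rank cutoff is ambiguous at exactly 15; both
  readings are implemented, defaulting to inclusive (see the similarity
  section).
- Printed similarity-table inputs are reproduced for 23 of the 24 published
  first-month verdicts; one published depth row is internally inconsistent
  with any cutoff rule (flagged early day, mean rank 14, yet not marked
  altered).
- The fight-time ~ weight regression computed from the packaged 20-fish
  deployment table (slope 0.146, R² 0.40) differs from the published
  coefficients, which appear to draw on the full 81-fish capture set that
  is not tabulated.
- Pipeline first-dive durations carry the ≤ 10-s smoothing bias described
  under Events.
- The temperature correction of depth is an exposed hook with a zero
  default, not a fitted model.
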