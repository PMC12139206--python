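# tunatag

Post-release behaviour analysis for archival-tagged Atlantic bluefin tuna
(*Thunnus thynnus*).

Catch-and-release tagging perturbs the behaviour of large pelagic fish, and
the perturbation can outlast the few hours usually discarded from tracking
records.  `tunatag` implements the full analysis chain needed to quantify
that perturbation from the two common record classes — high-rate archival
accelerometer tags (20–30 Hz tri-axial acceleration, "G7-style") and
low-rate pop-up archival tags (0.2 Hz, "MiniPAT-style"):

- **Activity metrics.** Static (postural) acceleration is separated from
  dynamic acceleration with a 2-s running mean; activity is the vectorial
  dynamic body acceleration, VeDBA(t) = ‖(aₓᵈ, aᵧᵈ, a_zᵈ)‖.  A complex
  Morlet continuous wavelet transform (ω₀ = 6, 32 log-spaced periods in
  0.125–2 s) of the lateral channel yields tailbeat amplitude (TBA, the
  amplitude-calibrated ridge magnitude), dominant stroke frequency (DSF)
  and tailbeat period (TBP = 1/DSF).
- **Immediate response.** Release-aligned hourly means for the first 24 h,
  the first-hour activity ratio, and a stabilisation (plateau) hour from a
  fitted exponential decay A·e^(−kh) + C (plateau when the residual falls
  to 5 % of A).
- **Events.** The first dive (first excursion > 10 m lasting ≥ 20 s), whose
  duration scales with fight time; fast starts (VeDBA strictly above the
  deployment-wide 99th percentile); inactive days (< 1 % of the day in fast
  starts).
- **Diel similarity test.** Each day becomes a 24-h profile of hourly mean
  VeDBA (or depth); over a 30-day block every day is correlated with every
  other (zero-lag Pearson, pairwise-complete), a day's similarity value is
  the median of its 29 correlations, days are ranked 1–30, the ranks are
  shuffled 10,000 times, and days at or below the empirical 5th percentile
  of their resampled null are flagged dissimilar.  The first post-release
  week is *altered* when ≥ 1 of days 1–7 is flagged and the mean rank of
  days 1–7 falls in the lower half of the scale.
- **Movement.** Daily great-circle steps and turning angles feed a 2-state
  hidden Markov model (gamma step lengths, von Mises angles) fitted by
  multi-start direct maximisation of the forward likelihood, with Viterbi
  decoding, PIT pseudo-residual diagnostics, straightness indices, and a
  mixed model of log mean depth on day/night × movement state.
- **Synthetic tag records.** Because raw field archives are not deposited,
  `tunatag.simulate` generates acceleration, depth and track records whose
  ground truth matches the analyses' assumptions (activity burst, subdued
  phase, diel structure, fight-time-dependent first dive, injected fast
  starts, two-state movement), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from tunatag import SimScenario, simulate_accel
from tunatag.accel import activity_series, hourly_means, burst_ratio, plateau_time
from tunatag.tailbeat import tailbeat_metrics

scn = SimScenario(duration_days=25/24, accel_fs=20.0, rng_seed=2)
series = simulate_accel(scn)
act = activity_series(series)
hourly = hourly_means(act.vedba, series.fs, 24)
print(f"first-hour activity ratio: {burst_ratio(hourly):.2f}")
print(f"plateau hour: {plateau_time(hourly)}")
i0 = int(12 * 3600 * series.fs)
tb = tailbeat_metrics(act.dynamic["ay"][i0:i0 + 12000], series.fs)
print(f"DSF {np.nanmedian(tb.dsf):.2f} Hz, TBA {np.nanmedian(tb.tba):.3f} g")
```

prints

```
first-hour activity ratio: 2.39
plateau hour: 7
DSF 1.16 Hz, TBA 0.059 g
```

i.e. the fish was 2.4× more active in its first hour than over the rest of
the day, activity stabilised 7 h after release, and the tailbeat oscillator
(1.18 Hz at 0.06 g in this scenario) is recovered through the static-split
and wavelet chain.

A command-line interface wraps the same pipeline:

```
tunatag simulate --out sim/ --seed 3 --n-fish 3 --days 30 --fs 0.2
tunatag cohort --input-dir sim/ --out-dir results/ --seed 3
```

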