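# Methods

This note documents the models, parameters and numerical choices behind
`ppgval`, and what the synthetic tests do and do not establish about real
recordings.

## Data model and conventions

All times are integer milliseconds since the Unix epoch (UTC); display
formats are presentation only. An interbeat interval (IBI) is anchored at
the beat that **closes** it: the onset stored for interval *i* is the
timestamp of the second of its two delimiting beats. Wearable exports do
not document whether their timestamps mark interval start or end; the
closing-beat convention was chosen once and is applied consistently
everywhere, including window membership during segmentation. Duplicate
timestamps on ingest keep the first occurrence and warn. Condition windows
are half-open `[start, end)`, so abutting windows partition beats without
double counting.

## Synchronization

Device clocks are assumed to differ from the criterion clock by a single
constant offset (no drift correction). Both beat series are converted to
instantaneous-rate step functions — 60000/IBI, held constant over each
interval — sampled on a uniform grid (default 4 Hz, matching the spectral
resampling rate), and the integer-grid lag in ±`max_lag_s` (default 60 s)
maximising the Pearson correlation of overlapping samples is chosen; ties
break toward the smallest |lag|. Grid samples falling in intervals outside
300–2000 ms, or outside 0.65–1.5× the series' median interval, are treated
as missing: such intervals are recording gaps, merged beats (≈2× the heart
period) or split beats, and their implausible instantaneous rates otherwise
dominate the correlation. With this masking, a stream with 8% missed beats
and 8 ms timing jitter still aligns at correlation ≈ 0.96; estimates with
peak correlation below 0.3 are flagged for manual review, and a per-device
`lag_override` bypasses estimation entirely. The returned lag is how far
the device clock runs *ahead* of the criterion; applying it subtracts that
amount. At least 60 s of mutual overlap is required.

## Artifact correction

Two rules, applied per segment in fixed order, define artifacts:

1. **Range rule** — IBIs strictly below 300 ms or above 2000 ms
   (boundaries kept).
2. **Karlsson neighbour-mean rule** — interior interval *i* is an outlier
   when |IBI_i − m| > c·m, m the mean of its two index neighbours; the
   first and last intervals are never flagged.

Neighbour means use the original values and all flags are decided
simultaneously; sequential re-evaluation would make the result depend on
scan order. Flagged values are replaced by linear interpolation over beat
*index* between the nearest unflagged neighbours (runs interpolate across
the run; flagged extremes copy the nearest unflagged value); onsets are
untouched, so cleaning conserves length. One Karlsson pass is applied per
cleaning call — no iteration to a fixed point — which matches the rule as a
formula; on physiological series with isolated artifacts the pass is
idempotent (verified by test), though pathological series where most beats
flag each other need not be.

The coefficient c starts at 0.25 and escalates in 0.05 steps, per
participant, until the criterion ECG segments (already visually scored,
hence presumed artifact-free) show zero flags; that personalised threshold
is shared across all of the participant's devices and conditions, avoiding
over-correction of individuals with naturally high variability. A hard cap
of 1.0 raises an error advising manual review — an escalation that far
means the "clean" criterion is not. The artifact count per segment is the
union of both rules' flags.

## Features

* **Mean HR** = 60000 / mean(IBI), bpm.
* **RMSSD** = √(Σ(IBI_i − IBI_{i−1})²/(N−1)), ms; needs ≥ 2 intervals.
* **HF power**: the IBI series is resampled onto a uniform 4 Hz grid over
  the segment span, mean-centred, a Welch periodogram is computed (Hann
  window, 256-sample segments or the whole grid if shorter, 50% overlap,
  no further detrending), and power is integrated over 0.12–0.40 Hz —
  the 7.2–24 breaths/min respiratory band — by the trapezoidal rule with
  PSD values interpolated at the exact band edges. Units ms². Segments
  spanning under 60 s return no value: a Welch estimate with ≲ 2 band
  cycles per window is meaningless.

The grid interpolation is a **cubic spline**, not piecewise-linear.
Linear resampling of a tachogram sampled at the beat rate (~1.1 Hz at a
900 ms heart period) acts as a low-pass filter that removes ~25–30% of
true respiratory-band power: on a pure 0.25 Hz, 50 ms-amplitude
modulation whose in-band power is analytically 50²/2 = 1250 ms², linear
interpolation yields ≈ 890 ms² while the cubic spline yields ≈ 1229 ms²
(−1.7%), with out-of-band leakage below 0.1 ms². Welch parameters are
recorded in the report metadata so they are auditable; HF values from
other Welch settings are not directly comparable.

## Signal quality

Per participant × device × condition: *missing* when the device recorded
nothing (connection failure, lost data) — a device-level failure, so a
window with data elsewhere but zero beats inside counts as *poor* (a 100%
count deficit), not missing. *Poor* when |n_device − n_criterion| /
n_criterion > 0.30 (symmetric in direction, strict) or n_artifacts /
n_device > 0.30 (strict). The detection rate is 100·n_device/n_criterion
over non-missing segments. Cohort tables report percent poor/missing/
acceptable (summing to 100 per cell), artifact mean ± SD, and mean
detection rate.

## Movement

Accelerometer counts are scaled by sensitivity = physical range / digital
range (calibration offset assumed zero: two's-complement counts centred at
0), high-passed per axis with a first-order Butterworth at 0.1 Hz applied
forward–backward — zero-phase, so filter lag cannot smear condition
boundaries; condition means are insensitive to this choice at reported
precision — then combined as the per-sample Euclidean norm and averaged
within each window. The sample rate comes from configuration, never
assumed.

## Agreement statistics

Observations are participant-level feature values within one device ×
condition cell, pairwise complete, n reported per cell. MAAPE is
100 × mean(arctan(|d − c|/|c|)), arctan in radians; the ×100 percent scale
puts its asymptote at 100·π/2 ≈ 157.08. Its CI is t-based on the
per-participant arctan terms. Regression is OLS of device on criterion
(`scipy.stats.linregress`), with correlation bands on |r| (boundaries
assigned upward: r = 0.90 is "very high"). Bonferroni adjustment
multiplies the slope p-value by the family size, by default devices ×
conditions per feature, configurable and logged. Bland–Altman differences
are device − criterion; bias CI uses t(n−1)·SD/√n and each LoA CI the
large-sample variance 3σ²/n with z = 1.96. RMSSD and HF are
ln-transformed before regression and Bland–Altman (right-skewed), never
before MAAPE. Poor-quality segments are **included** by default — in the
field there is no criterion available to screen them out, so excluding
them flatters the device; `exclude_poor` enables the sensitivity analysis.

## Synthetic generator

The criterion stream accrues beats iteratively: the next interval is
mean_ibi + A·sin(2πf·t) + N(0, σ), modelling respiratory sinus arrhythmia
as a single sinusoid — enough to give HF a closed-form target (A²/2) —
plus white beat-to-beat noise. Defaults: 900 ms mean (≈ 67 bpm), A = 50 ms
at f = 0.25 Hz (15 breaths/min, mid-band), σ = 25 ms in cohort studies,
300 s duration. A config invariant (mean − A − 4σ > 300 ms) keeps the
truth inside the physiological range. Device streams are derived by
corrupting reconstructed *beat times* (so merge/split semantics are
exact), in order: constant clock offset; per-beat deletion (miss rate);
per-interval insertion at a uniform 0.2–0.8 split point (spurious beats);
Gaussian timing jitter; dropout windows. All draws are deterministic under
the config seed. Simulated accelerometer traces superimpose band-limited
(0.3–8 Hz) Gaussian noise on a constant 1 g z-axis gravity vector, with
per-axis SD calibrated so the post-filter mean vector magnitude equals the
requested movement level (for an isotropic Gaussian vector the mean
magnitude is 2σ√(2/π)); sedentary windows target ≈ 0.01 g and walking
≈ 0.16 g.

What the generator does **not** model: PPG waveform morphology and
device-specific peak-detection behaviour, movement-correlated (rather than
independent) beat loss, clock drift, skin-tone or BMI effects, and
non-sinusoidal or non-stationary respiration. Passing the synthetic
recovery tests therefore shows the pipeline's bookkeeping and statistics
are correct under known corruption — not that any particular physical
device is valid.

## Problem sizes and defaults in tests

Cohort-level tests and the acceptance script use 3–5 simulated
participants with 2–3 two-minute conditions or the full eight-condition
protocol at 4–8 participants — sizes chosen so the whole suite documents
the pipeline's behaviour in seconds while every statistic still has ≥ 3
pairs per cell. The study-scale defaults (eight conditions: 5 min sitting,
10 min neurotask, 3 min otherwise) are configuration, not constants.

## Known limitations

* Synchronization assumes a constant offset; drifting clocks would need
  piecewise alignment.
* The adaptive threshold trusts the criterion to be artifact-free; a noisy
  criterion inflates thresholds for all devices of that participant.
* One Karlsson pass per cleaning call can leave adjacent-artifact clusters
  partially corrected (inherent to the neighbour-mean rule).
* HF power depends on resampling and Welch settings; values are comparable
  only within one configuration.
* Avro peak files are not read; peak trains interchange as plain
  single-column CSV.
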