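# ppgval

Toolkit for validating wearable photoplethysmography (PPG) heart-rate and
heart-rate-variability streams against a criterion electrocardiogram (ECG).

Psychophysiology labs increasingly use optical wrist-, arm- or ear-worn
sensors in place of ECG. Before trusting them, the beat-to-beat interval
(IBI) stream of each candidate device must be scored against a reference:
how many beats does it find, how clean are they, and how well do the
derived measures — mean heart rate, RMSSD and high-frequency (HF)
spectral power — agree with the ECG's? `ppgval` implements that whole
validation pipeline:

1. **Ingest** — timestamped IBI exports (plain CSV, HRV-Logger-style CSV,
   whitespace-separated criterion text), systolic-peak files
   (`ibis[i] = peak[i+1] − peak[i]`), tri-axial accelerometer counts, and
   a condition-window table.
2. **Synchronize** — each device clock is aligned to the criterion by
   maximising the Pearson cross-correlation of instantaneous-rate step
   functions resampled on a 4 Hz grid (with a manual lag override).
3. **Segment** — streams are sliced into named condition windows
   (half-open `[start, end)`, membership by the beat closing each
   interval).
4. **Clean** — artifacts are corrected per segment: IBIs outside
   300–2000 ms, then the Karlsson neighbour-mean rule — interval *i* is an
   outlier when |IBI<sub>i</sub> − m| > c·m with
   m = (IBI<sub>i−1</sub> + IBI<sub>i+1</sub>)/2. The coefficient starts
   at c = 0.25 and escalates in 0.05 steps, per participant, until the
   (already clean) criterion shows no outliers; flagged values are
   replaced by linear interpolation.
5. **Features** — per segment: HR = 60000 / mean(IBI);
   RMSSD = √(Σ(ΔIBI)²/(N−1)); HF power = Welch PSD of the 4 Hz-resampled
   IBI series integrated over 0.12–0.40 Hz (the 7.2–24 breaths/min
   respiratory band), in ms².
6. **Quality** — a segment is *missing* when the device recorded nothing,
   *poor* when its beat count deviates more than 30% from the criterion's
   or artifacts exceed 30% of detected IBIs, else *acceptable*; plus the
   IBI detection rate (device count / criterion count × 100).
7. **Movement** — accelerometer counts × (physical/digital range) → g,
   0.1 Hz first-order high-pass, Euclidean magnitude, per-condition means.
8. **Agreement** — per device × condition × feature on participant-level
   pairs:
   * MAAPE = 100 · (1/N) Σ arctan(|device − criterion| / |criterion|),
     bounded by 100·π/2 ≈ 157.08;
   * OLS regression of device on criterion (slope, intercept, Pearson *r*
     with Mukaka bands, Bonferroni-adjusted *p*, SE);
   * Bland–Altman: bias = mean(device − criterion), limits of agreement
     bias ± 1.96·SD, with t-based bias CI and 3σ²/n LoA CIs. RMSSD and HF
     are ln-transformed before regression/Bland–Altman.

A synthetic generator produces paired criterion/device streams with known
ground truth — respiratory sinus arrhythmia as a sinusoidal heart-period
modulation, plus missed beats, spurious beats, timing jitter, dropouts and
clock offsets — so every stage is testable without any recordings.

## Worked example

Generate a 4-participant synthetic study (three simulated devices: `good`
= perfect but 5 s off-clock, `lossy` = 8% missed beats + jitter, `flaky`
= dropouts and one participant in four with no recording) and run the
full pipeline:

```sh
ppgval simulate --out demo --participants 4 --seed 3
ppgval run --config demo/study.yaml
```

```
wrote synthetic study for 4 participants to demo
analyzed 4 participants; 69 agreement cells -> demo/out
```

`demo/out/agreement.md` then contains, for the perfect device:

```
| Device | Condition | Feature | MAAPE (CI)        | r [band]         | Bias (LoA)        | n |
| good   | sitting   | hr      | 0.00 (0.00, 0.00) | 1.00 [very high] | 0.00 (0.00, 0.00) | 4 |
| good   | sitting   | rmssd   | 0.00 (0.00, 0.00) | 1.00 [very high] | 0.00 (0.00, 0.00) | 4 |
```

i.e. after the 5 s clock offset is recovered automatically, the device's
features are identical to the criterion's: zero error (MAAPE 0%), perfect
correlation, zero bias with degenerate limits of agreement. The flaky
device's rows in `demo/out/quality_table.md` show the planted failures
instead:

```
| Device | Condition  | Poor % | Missing % | Artifacts mean (SD) | Mean IBI detection rate % |
| flaky  | arithmetic | 0.0    | 25.0      | 13.67 (9.45)        | 97.51 |
```

— 25% missing (1 of 4 participants had no recording) and the artifacts
produced by its missed beats. The accelerometer summary recovers the
planted movement contrast (sitting ≈ 0.01 g, walking ≈ 0.159 g, biking
≈ 0.08 g).

The library mirrors the CLI: `read_ibi_csv`, `estimate_lag`, `segment`,
`clean_segment`, `hf_power`, `classify`, `agreement_stats`,
`analyze_cohort`, … — see the module docstrings.

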