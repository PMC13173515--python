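# Methods

This note documents the models, algorithms, parameter defaults and numerical
conventions implemented in `rqtecg`, and what the synthetic-data tests do and
do not demonstrate about real recordings.

## The RQT differential

Per beat, with `RRI[i]` the interval following beat *i*'s R peak (ms) and
`QT[i]` the beat's Q-onset-to-T-offset duration (ms):

```
QTc[i]       = QT[i] / sqrt(RRI[i] / 1000)         (Bazett)
RQT_diff[i]  = RRI[i-1] − QTc[i-1],   defined for i ≥ 2
```

The differential is anchored two beats into the record: its first two slots
are always absent, and a three-beat record yields exactly one value. The
identity `RQT_diff[i] − (RRI[i-1] − QTc[i-1]) = 0` is asserted to 1e-9 ms on
every defined element of every assembled series — it is the module's cardinal
invariant and cannot silently drift.

Units are milliseconds throughout; seconds appear only inside the
correction-formula root. This deliberately avoids the unit-mixing bug the
mixed clinical convention invites. Supported corrections:

| method     | formula (QT in ms, RRI_s = RRI/1000)        |
|------------|---------------------------------------------|
| bazett     | QT / sqrt(RRI_s)                            |
| fridericia | QT / RRI_s^(1/3)                            |
| hodges     | QT + 1.75·(60000/RRI_ms − 60)               |

Bazett and Fridericia agree exactly at RRI = 1000 ms; Hodges is the additive
heart-rate form. An optional artifact pre-filter flags intervals outside
300–2000 ms or deviating > 20 % from an 11-beat running median; it is **off
by default** because the intended inputs are sinus-rhythm recordings.

### Lag-consistent HRV alignment

When the RRI and RQT-diff series are analysed jointly, each RQT-diff value is
paired with the RR interval it derives from (`aligned_hrv_inputs`): element
*k* carries `RRI[j]` and `RQT_diff[j+1]` at the time of beat *j*. Under a
constant QTc this makes the RQT-diff series exactly the RR series minus a
constant, so every index — all four are offset-invariant — agrees on the two
series to machine precision. This is the construction the acceptance suite
checks at 1e-6.

## Synthetic generator

Each beat is a sum of Gaussian kernels (P, Q, R, S plus one or two T lobes),
in the spirit of the ECGSYN dynamical model but assembled beat-by-beat so
that ground truth is analytic:

* P (0.12 R, −190 ms, σ 22 ms), Q (−0.10 R, −28 ms, σ 7 ms),
  R (1.0, 0 ms, σ 10 ms), S (−0.18 R, +32 ms, σ 8 ms).
* T lobes per class: monophasic ±1.0 (σ 20 ms); biphasic ±(1.0, 0.8) at
  70 ms separation (σ 16 ms); notched (1.0, 0.9) at 55 ms (σ 16 ms); flat is
  a monophasic lobe whose amplitude fraction sits at or below the flatness
  threshold.
* True Q onset = the 1 %-of-amplitude point of the Q kernel
  (−28 − 3.035·7 ≈ −49 ms before R). True T offset = last sample where the
  noise-free T component stays ≥ 1 % of its own peak — a documented constant
  that keeps truth independent of additive noise. True T peak = extremum of
  largest |amplitude| of the T component.

RR dynamics: `RR_i = mean_rr + lf_amp·sin(2π·lf_freq·t_i) +
hf_amp·sin(2π·hf_freq·t_i) + N(0, rr_noise_sd)`, cumulative beat times.
Defaults emulate a middle-aged sinus-rhythm subject: mean RR 900 ms, LF
25 ms at 0.1 Hz, HF 15 ms at 0.3 Hz, jitter 10 ms, T at 35 % of R, sampling
500 Hz. Frequencies outside the canonical LF (0.04–0.15 Hz) and HF
(0.15–0.40 Hz) bands are allowed but logged.

QT–RR coupling stretches each beat's Q-onset→T-offset duration to
`qt_alpha·(RR/1000)^qt_beta`, where RR is the interval *following* the R
peak — the same pairing the interval layer's correction uses, so the default
`qt_alpha = 400 ms, qt_beta = 0.5` produces a world with exactly constant
Bazett QTc. (Physiological QT adaptation tracks preceding intervals with
hysteresis; the forward pairing is a deliberate simplification that makes
the constant-QTc construction exact.)

One global seed drives everything; per-component generators are spawned
deterministically from it, so records are byte-reproducible.

**What the generator does not emulate:** ectopy and arrhythmia, respiratory
amplitude modulation, electrode artifacts, QT hysteresis, P-wave variation,
and real morphological heterogeneity within a record. Perfect recovery on
synthetic records therefore demonstrates internal consistency of the
delineator with its waveform model — not clinical-grade accuracy, which is
what benchmarking against expert-annotated databases (the `benchmark`
operation) is for.

## Delineation

1. **Band-pass 0.5–40 Hz**, 2nd-order Butterworth applied forward-backward
   (zero phase) so fiducial timing is not shifted. Records shorter than
   three low-corner impulse-response lengths (~3·fs/0.5 samples) are
   rejected.
2. **R peaks — Pan–Tompkins**: 5–15 Hz band-limit, derivative, squaring,
   150 ms moving-window integration; adaptive dual thresholds
   (`THR = N + 0.25·(S − N)` with the usual 0.125/0.875 running updates),
   200 ms refractory, searchback at half threshold when a beat is overdue
   (> 1.66× the running RR mean), and the classic T-wave discrimination
   rule: a candidate within 360 ms of the last beat with less than half its
   slope is repolarization, not a beat. A scale-invariant quality gate
   rejects beat-free noise (integrated energy peak < 8× the record median —
   QRS complexes tower over the noise floor by an order of magnitude).
   Detections are refined to the extremum of |filtered signal| within
   ±50 ms, which also makes detection polarity-robust; a record whose median
   R amplitude is negative is analysed on the inverted signal.
3. **Q onset**: in a 150 ms window before R (configurable 100–150 ms), find
   the Q minimum, then walk backward while the descending slope stays above
   2 % of the beat's peak slope. On sampled data the first derivative of a
   smooth beat never crosses zero exactly between the P tail and the Q dip,
   so the slope-threshold walk-back is the practical form of the
   zero-crossing rule; the threshold is relative, preserving scale
   invariance. Without a Q dip the same walk-back starts from the R
   upstroke and returns the QRS onset. A window extending before the record
   start skips the beat (logged, never fatal).
4. **T wave**: search window `[R+200 ms, R+min(500 ms, 0.7·RRI)]` — the
   window shrinks at fast rates. Baseline = median of the 40 ms PR segment
   before the beat's Q onset. The windowed segment is lightly smoothed
   (12 ms moving average) and classified:
   flat if max |T| < 0.10·R; else significant extrema (prominence ≥ 25 % of
   max |T|) decide — two opposite-sign lobes → biphasic by order, two
   same-sign lobes ≥ 40 ms apart → notched, one lobe → monophasic by sign.
   All thresholds are fractions of the beat's R amplitude, so labels are
   invariant to positive rescaling of the record.
5. **T offset** (on the rectified final lobe, so negative and closing lobes
   are handled uniformly):
   * `baseline_threshold` — first sample after the last extremum below 10 %
     of its amplitude;
   * `tangent` — intersection of the tangent at the maximum downslope with
     the baseline;
   * `second_derivative` — first curvature sign change after the maximum
     downslope (falling back to the curvature maximum on clean decaying
     lobes).
   `auto` picks per morphology: tangent for monophasic waves (their steep
   downslope is well defined), return-to-baseline for biphasic, notched and
   flat. On clean Gaussian templates the tangent lands ~1σ early and the
   baseline rule ~0.9σ early — measured medians 10–20 ms across classes, an
   early bias consistent with automated-delineation practice. The
   second-derivative point sits earlier still (~28 ms on biphasic
   templates), which is why `auto` does not use it; it remains available by
   configuration.
6. **Flat waves abstain.** When the T amplitude is below the flatness
   threshold the delineator reports the morphology but leaves t_peak/t_off
   absent rather than returning a fiducial dominated by noise. Downstream
   QT/QTc/RQT-diff slots propagate the absence; benchmarking excludes
   low-amplitude-T beats by the same logic (quality screen at 15 % of R).

Ties between equal extrema break toward the earlier sample. The last beat
gets a T search only if the full window fits before the record end.

## HRV indices

All indices are invariant to constant offsets; SSR and the entropies are
additionally invariant to positive rescaling (tolerances scale with the SD;
SD1/SD2 is a ratio).

* **LHR** = LF power / HF power, LF = [0.04, 0.15) Hz, HF = [0.15, 0.40] Hz
  (the shared boundary belongs to HF — an arbitrary, documented convention).
  Estimated by Lomb–Scargle directly on the unevenly sampled beat series,
  integrated over the bands at 1 mHz resolution; avoids interpolation bias.
  A 4 Hz cubic-resampled Welch estimator is provided as a cross-check.
  Requires ≥ 120 s and ≥ 50 beats.
* **SSR** = mean over lags m = 1..10 of SD1_m/SD2_m, where
  SD1_m = sd((x[i+m]−x[i])/√2) and SD2_m = sd((x[i+m]+x[i])/√2). A zero SD2
  at any lag (constant or strictly alternating input) is an error, detected
  with a relative tolerance so floating-point dust cannot masquerade as
  variance.
* **Sample entropy**: SampEn = −ln(A/B) with Chebyshev distance,
  self-matches excluded, both A and B counted over the n−m templates that
  can extend to length m+1 (the standard convention). Defaults m = 2,
  r = 0.2·sd. The vectorized pair counting is verified against an explicit
  O(n²) loop in the test suite — exact count equality, not approximate.
* **MSE_SS** = mean SampEn over coarse-graining scales 1..5, with r fixed
  from the scale-1 series. Scales 1..5 keep ≥ 50 coarse points from ≈ 300
  beats and are exposed in configuration.
* **BEI**: the published formula lives in prior work not reproduced here,
  so the implementation is a declared stand-in honouring the verbal
  definition — the sample entropy of heart-rate fluctuations in the
  baroreflex/LF band: resample the beat series at 4 Hz (cubic spline),
  zero-phase band-pass 0.04–0.15 Hz, sample back at the beat times, SampEn
  with m = 2, r = 0.2·sd of the filtered series. It lives behind a named
  plugin registry (`BEI_IMPLEMENTATIONS`) so an exact formula can replace it
  without interface changes. Numbers derived from BEI are
  stand-in-dependent and should be labelled as such.

Absent beats are dropped; beat times keep the survivors' true times (the
Lomb–Scargle estimator tolerates gaps), entropies use the gap-naive
concatenated series with a warning when > 5 % of beats are missing.

## Evaluation

* **Benchmarking**: reference beats with T amplitude < 15 % of R are
  excluded (the quality screen); R peaks matched one-to-one greedily by
  distance within 150 ms (a standard beat-matching window, configurable);
  errors are signed detected-minus-reference, so a negative QT median means
  the automatic T offset lands early. A QT detection counts as positive
  when its beat's R is matched and both Q and T offset were produced, and
  as spurious when its beat's R is unmatched.
* **ROC**: rank/trapezoid AUC, reported for the orientation where higher
  scores predict the positive class (the chosen orientation is returned);
  optimal cutoff by Youden's J.
* **Logistic regression**: maximum-likelihood fit of
  `logit P = B0 + B1·index + B2·covariate` (BMI by convention), Wald 95 %
  CIs on the odds-ratio scale, Hosmer–Lemeshow over 10 risk deciles (stable
  sort for ties), accuracy at probability 0.5. Perfect separation is
  detected and reported as a distinct condition, never silently fitted.
* **Morphology tabulation**: per-subject type = modal per-beat clinical
  label, ties broken toward the abnormal label (conservative clinical
  reading); percentages to one decimal.
* The shape classes map to clinical types as: monophasic-positive → A
  (normal) unless its amplitude reaches 60 % of R → C (peaked); flat → B;
  monophasic-negative → D (inverted); biphasic and notched → E (other). The
  peaked type has no shape-class counterpart, so the amplitude bridge is a
  design decision, exposed as `peaked_frac`.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic data:
100-beat records per morphology class for delineation recovery, 280–300
beats for interval/HRV pipelines (≥ 250 beats keeps ≥ 50 coarse points at
MSE scale 5), 600-beat tachograms for spectral checks, n = 5000 for the
i.i.d. Poincaré check, and a 30-subject two-arm cohort for the ROC
demonstration. These sizes were chosen so each property is measured with
comfortable margin at desk scale. Every random quantity derives from a
single seed; identical seed and configuration reproduce byte-identical
pipeline outputs (asserted in the acceptance suite).

## Known limitations

* The delineator targets Lead II sinus rhythm; no P-wave delineation,
  multi-lead fusion, or arrhythmia handling.
* WFDB support covers format-16 signals and the standard annotation
  mnemonics used by QT-database-style files; other signal formats are
  rejected explicitly.
* BEI is a stand-in (above).
* The second-derivative T-offset rule is biased early on smooth lobes;
  it is kept for completeness and cross-method comparison.
* Clinical cohort statistics (group means, regression tables) depend on
  patient data this package does not ship; the evaluation module provides
  the operations, not the cohort results.
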