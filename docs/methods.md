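# Methods

`sedcut` implements an end-to-end pipeline for deriving sedentary-time
cut-points from raw thigh-worn accelerometry and validating them against a
criterion posture-event measure. Because no public raw data exist for this
design, the package ships a first-class synthetic-data generator whose
defaults emulate the study conditions; all quantitative checks run on that
generator.

## Signal model

A recording is tri-axial acceleration in g at a fixed rate (default 20 Hz,
dynamic range ±4 g, the device defaults). The simulator composes each
posture/activity bout as

```
a(t) = r(t) · u(t),     r(t) = 1 + c + A sin(2π f t + φ)
```

where `u(t)` is a unit orientation vector (gravity direction in the sensor
frame) and `r(t)` a magnitude waveform. The sensor then distorts the ideal
signal per axis as `gain · a + offset`, adds white noise, and clips to the
dynamic range.

* **Orientation.** The x-axis runs along the thigh. Upright postures place
  gravity within 15° of +x; lying and sitting place it within 20° of the
  horizontal (y–z) plane, with per-bout jitter. In-bed orientation is drawn
  uniformly on the sphere (sleepers adopt arbitrary thigh positions), which
  also gives the calibration fit its sphere coverage. Still postures drift
  by a few degrees every few minutes (piecewise rotations: 8–25° per
  adjustment while sitting/standing, 15–40° in bed). This models postural
  adjustment, keeps `|a| = 1` exactly during stillness, and is what keeps
  genuine wear from being mistaken for non-wear. Non-wear itself is the
  device lying flat and truly motionless.
* **Amplitude.** The oscillation frequency is drawn from multiples of
  0.2 Hz in 0.8–2.4 Hz so every 5-s epoch holds an integer number of cycles.
  Given per-bout targets for the two epoch metrics, the offset `c` and
  amplitude `A` are solved by root finding on closed-form normal
  expectations (the expected epoch ENMO of `max(c + A sin θ + σZ, 0)` and
  the expected epoch MAD of `|A sin θ + σZ|`, averaged over a phase grid),
  so realised epoch values hit the targets under the sensor's noise σ.
* **Between-participant variation.** Bout targets are drawn log-normally,
  with the median and the Q1–Q3 range matched to the laboratory activity
  summaries (e.g. pooled sedentary ENMO 5.1 (3.1–8.6) mg, self-paced walk
  MAD 316.3 (268.7–370.2) mg), using a single latent factor per bout so the
  two metrics co-vary.

## Laboratory protocol

The scripted session holds 12 activities — 4 lying, 2 sitting, 6 upright —
of 5 min each (stairs: 2 min), separated by 30-s quiet-standing breaks and a
2-min break before stairs; a 3-min lead-in/lead-out pads the session to
70 min (840 five-second epochs). Epoch values are reduced to per-participant
per-activity means after trimming the first and last 30 s of each bout
(48 contributing epochs for a 5-min activity). Lab recordings are generated
without gain/offset miscalibration: such short files lack the varied
stationary postures auto-calibration needs, the situation in which a
well-characterised device's back-up coefficients are used.

## Free-living behaviour model

Defaults (all overridable via `BehaviourParams`):

* **Time in bed** 23:00–07:00 with ±20 min nightly jitter; one in-bed event
  per night, internally split into 20–60 min orientation segments.
* **Sedentary fraction of waking time** per participant ~ N(0.5717, 0.0886),
  clipped to (0.35, 0.80), with ±0.03 day-to-day variation. With a 960-min
  waking day this makes the cohort-mean criterion sedentary time ≈549 min/d
  with an ≈85 min/d between-participant SD, the reported free-living level.
* **Bout structure.** Waking time alternates sedentary bouts (truncated
  exponential, mean 30 min) and upright bouts (mean 20 min), rescaled so the
  day's sedentary share hits its target; all boundaries snap to the 5-s
  epoch grid, so criterion minutes are recoverable exactly from the emitted
  event series.
* **Upright composition** (time weights): 4% quiet standing, 61% light
  "puttering" (household movement), 35% walking, in 0.5–4 min segments.
  Standing and sedentary segments draw their epoch targets from the
  laboratory standing/sedentary distributions. Walking reuses the laboratory
  walking signature scaled by a log-normal factor (median 0.55, σ=0.35):
  free-living ambulation is slower than a lab walk. Puttering is synthesised
  as a **zero-mean** magnitude oscillation (`c = 0`) with MAD target
  log-normal (median 85 mg, σ=0.45).

The zero-mean choice for light movement is deliberate and is the mechanism
behind the ENMO/MAD asymmetry the pipeline is meant to exhibit: when the
magnitude swings symmetrically about 1 g, the expected ENMO is `A/π` while
MAD is `2A/π`, so ENMO reads about half of MAD for the same movement.
Sustained lab activities, in contrast, carry a positive magnitude offset.
With cut-points of similar size for both metrics (both near 30 mg), a larger
share of light free-living movement falls below the ENMO cut-point than
below the MAD cut-point, so an ENMO cut-point over-counts sedentary time —
the qualitative free-living finding this package reproduces. These
behaviour-mix values were fixed from this design reasoning, not tuned to any
test outcome.

What the generator does **not** model: gait harmonics and impact spectra,
heart-rate/EE correlates, device detachment artefacts other than flat
motionless non-wear, temperature-dependent calibration drift, and any
dissociation between posture and movement (e.g. pedalling while seated). A
passing suite therefore shows the pipeline's statistics are correct and that
the qualitative metric asymmetry follows from the stated signal model — not
that the derived thresholds transfer to human data.

## Calibration

Stationary windows are 10-s non-overlapping blocks with per-axis SD < 13 mg
(windows containing range-clipped samples are discarded). Window means are
fitted to the unit sphere by an iteratively re-weighted per-axis linear
regression (`calibrated = gain·x + offset` toward each point's closest
sphere position, weights `min(1/|‖p‖−1|, 100)`), stopping when the mean
squared residual changes by <1e-9 or after 100 iterations. The fit requires
≥10 stationary points spanning both signs beyond ±300 mg on every axis;
otherwise — and whenever fitting would not reduce the error — the identity
model is returned flagged non-converged so callers can substitute back-up
coefficients. Post-calibration error is the mean |‖point‖ − 1| after
correction; files qualify below 0.02 g.

## Epoch metrics, non-wear, imputation

ENMO truncates per sample before averaging: `max(‖a‖ − 1, 0)`, epoch mean,
in mg. MAD is the mean absolute deviation of `‖a‖` about the epoch's own
mean. Epochs are half-open 5-s windows; a trailing partial epoch is dropped.
Non-wear detection classifies 15-min blocks by their surrounding 60-min
window (per-axis SD < 13 mg and range < 50 mg on ≥2 axes), broadcast to the
epoch grid — the processing defaults of the field's standard raw-data
software. Non-wear epochs are imputed by the mean of worn epochs at the same
clock slot on the other recorded days; slots with no donor stay flagged and
invalidate their day. Imputed epochs do contribute to cut-point
classification (flagged in output); the alternative—counting them only
toward wear validity—was rejected to keep estimate and criterion windows
identical.

## Cut-points

The ROC unit of analysis is the per-participant per-activity mean (420
points for a 35-participant lab cohort); the positive (sedentary) class is
activities 1–6, predicted when the metric value falls below the threshold.
Candidate thresholds are midpoints between consecutive distinct values;
the Youden index J = sensitivity + specificity − 1 selects the optimum, ties
going to the larger threshold (an interior criterion). AUC is trapezoidal
and equals the Mann–Whitney pairwise statistic (property-tested); bands:
<0.70 poor, 0.70–0.79 fair, 0.80–0.89 good, ≥0.90 excellent. Two grouping
schemes exist: sedentary vs all upright activities, and sedentary vs
passive standing only (the standing-isolated ENMO variant; its AUC is poor
by construction because quiet standing and sitting produce near-identical
thigh accelerations).

## Free-living comparison

Analysis days are calendar days (midnight-to-midnight) with complete 24-h
coverage and no unimputable epochs. Time-in-bed intervals come from the
ground-truth in-bed events; each is labelled with the night of
`start − 12 h`, and a day's waking window subtracts every in-bed interval
intersecting it — identically for the criterion (event durations) and the
estimate (5-s epochs with metric < cut-point, half-open epoch-start
convention). Days lacking a bed record are dropped from both paths.

Agreement statistics per comparison method: MPE/MAPE with per-record percent
error `100·(criterion − comparison)/comparison` (so over-counting yields a
negative MPE; note a means-level ratio can differ in sign from the mean of
per-record ratios, which is why per-record residuals are exported);
Bland–Altman bias ± 1.96 SD on absolute and percent (pair-mean denominator)
scales; and the smallest symmetric equivalence zone — scanned in
1-percentage-point steps — around the criterion mean that contains the
two-sided 95% CI of the comparison mean, also expressed as a multiple of
the criterion SD to 0.1. The 95% CI (not the TOST-conventional 90%) is a
deliberate fidelity choice. The default unit of analysis is the
participant-level mean of daily values; day-level analysis is available via
`unit="day"`.

## Problem sizes and determinism

The shipped study sizes are those of the emulated design: 35 lab
participants and a 36-participant free-living cohort; the packaged cohort
run uses 6 days per participant, and calibration checks use 7-day
recordings over 10 seeds. All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence`, so every simulation is bit-reproducible.
Signal arrays are generated in float32 (sensor resolution is far coarser);
epoch statistics accumulate in float64.

## Known limitations

* The laboratory AUC for sedentary vs all-upright is high but not 1.0 here:
  quiet standing overlaps the sedentary acceleration range in the published
  activity summaries that drive the generator, so perfect separation is not
  reproducible from those summaries.
* Printed percent-scale limits of agreement in the emulated study are not
  arithmetically recoverable from its absolute limits and means; the percent
  Bland–Altman here is therefore a separate analysis on per-pair percent
  differences, and only the percent bias is expected to match the printed
  arithmetic.
* Equivalence is assessed literally as "comparison-mean CI inside the zone
  around the criterion mean", not as a paired-difference TOST; both appear
  in the applied literature and they differ when the two series are highly
  correlated.
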