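# sedcut

Sedentary-time cut-points for raw thigh-worn accelerometry: derivation in a
scripted laboratory protocol, validation against a criterion posture-event
measure in free-living wear.

## The problem

Thigh-worn inclinometers are the reference method for measuring sedentary
behaviour (sitting/lying at low energy expenditure), but their posture
output comes from proprietary software. Processing the *raw* tri-axial
signal instead — auto-calibration, epoch metrics, a threshold in mg — makes
sedentary estimates transparent and comparable across devices. This package
implements and evaluates that route for researchers in physical-behaviour
epidemiology:

* **ENMO** (Euclidean Norm Minus One): per sample `max(√(x²+y²+z²) − 1, 0)`,
  averaged over 5-s epochs, in mg.
* **MAD** (Mean Amplitude Deviation): mean |‖a‖ − r̄| of the vector magnitude
  about the epoch mean r̄, in mg.
* **Auto-calibration**: per-axis gain/offset fitted so stationary-window
  means lie on the unit (1 g) sphere; files qualify when the residual error
  is <0.02 g.
* **Cut-point derivation**: per-participant activity means from a 12-activity
  lab protocol, ROC analysis with the Youden index
  J = sensitivity + specificity − 1; sedentary is predicted when the metric
  falls below the threshold.
* **Free-living agreement**: daily sedentary minutes (cut-point vs criterion
  posture events, identical waking windows after sleep exclusion), compared
  by MPE/MAPE, Bland–Altman limits of agreement, and the smallest
  equivalence zone containing the 95% CI of the comparison mean.

Because the emulated study's human recordings are not public, the package
includes a synthetic-data generator (`sedcut.simulate`) producing raw 20-Hz
recordings with ground-truth posture events for both arms of the design;
see `docs/methods.md` for the signal and behaviour models.

## Worked example

Derive cut-points from a simulated 35-participant laboratory cohort and
evaluate them on a simulated 36-participant free-living cohort:

```python
from sedcut import MethodAgreement
from sedcut.cutpoints import CutpointModel
from sedcut.pipeline import run_lab_study, run_freeliving_study

lab = run_lab_study(n_participants=35, seed=2023)
mad = CutpointModel.from_summaries(lab.summaries, "mad", "sed_vs_nonsed").fit()
enmo = CutpointModel.from_summaries(lab.summaries, "enmo", "sed_vs_nonsed").fit()
print(mad.summary())

daily = run_freeliving_study(36, 6, {"mad": ("mad", mad.threshold_mg),
                                     "enmo": ("enmo", enmo.threshold_mg)},
                             seed=2023)
report = MethodAgreement.from_daily(daily, "est_mad_min", comparison="MAD").fit()
print(report.summary())
```

Output (seeds as shown):

```
ROC / Youden cut-point (MAD)
  positives (sedentary) : 210
  negatives             : 210
  threshold             : 33.6 mg (sedentary if value < threshold)
  sensitivity           : 0.967
  specificity           : 0.833
  Youden J              : 0.800
  AUC                   : 0.921 (excellent)
Agreement vs criterion — MAD (36 participants)
  criterion  :  564.1 ± 115.8 min/d
  comparison :  564.7 ± 108.5 min/d
  MPE  : -0.3 ± 2.8 %
  MAPE : 2.1 ± 1.9 %
  Bland-Altman bias : -1 min (LoA -32 to 31 min)
  Bland-Altman bias : -0 % (LoA -6 to 5 %)
  equivalence zone  : 7% of criterion mean (0.3 SD)
```

The MAD threshold (33.6 mg here) separates the sedentary activity means
from the ambulatory ones; applied to free-living data its daily estimates
track the criterion closely (MPE −0.3%, equivalence within a 7% zone). The
same run with the ENMO cut-point shows the characteristic over-count —
MPE −10.6%, bias −62 min/d, a 17% equivalence zone — because light
free-living movement registers about half as much ENMO as MAD, so more of
it falls below the ENMO threshold. The standing-isolated ENMO variant
(`scheme="sed_vs_passive_standing"`) reproduces the near-total overlap of
sitting and quiet standing at the thigh (AUC ≈ 0.53, "poor").

A command-line interface mirrors the library:
`sedcut simulate lab|freeliving`, `sedcut calibrate`, `sedcut metrics`,
`sedcut derive-cutpoints`, `sedcut freeliving`, `sedcut agree`
(`sedcut COMMAND --help` for options).

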