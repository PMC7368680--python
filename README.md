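# asfm3d

Quantitative, observer-independent grading of facial palsy from 3D motion
capture, plus the prognostic models used to forecast recovery in the acute
phase of Bell's palsy.

Subjective scales (House-Brackmann, Sunnybrook) are quick but rater-dependent
and blind to subtle change. `asfm3d` implements the objective alternative: a
patient wears a rigid reference helmet and 21 reflective facial markers, is
recorded at 30 Hz while performing five standard expressions (brow elevation,
gentle eye closure, open mouth smile, snarl, lip pucker), and the pipeline
turns the marker trajectories into a 0–100 gross bilateral-symmetry score:

```
score = 0.7·D + 0.3·V − A
```

* **D** — 100 × the mean *distance symmetry ratio*: for each expression, the
  maximal moving distance (MMD) of the analyzed landmark on the paralyzed
  side divided by its mirror on the intact side (brow B/b, upper eyelid C/c,
  nasal ala G/g, mouth corner H/h — the mouth corner is analyzed by both the
  smile and the pucker).
* **V** — the same for maximal moving speed (MMS).
* **A** — resting-asymmetry score: five static measures (distances G–H, G–I,
  C–D, E–H and the angle ∠CED) are compared right/left; each ratio outside
  its healthy reference interval adds 4 points (maximum 20).

Upstream of the score sit rigid head stabilization in the helmet frame
(least-squares Kabsch superposition of the helmet markers) and
Savitzky–Golay smoothing/differentiation of each landmark trajectory.
Downstream sit the prognostic layer — the first-month model
`y = 132.112 − 0.699·x` (x = ENoG degeneration %), the second-month model
`y = 13.457 + 0.384·x₁ + 0.823·x₂` (x₁ = SFGS, x₂ = gross motion score),
recovery dichotomies (SFGS ≥ 70 or H-B grade ≤ II = good), empirical
ROC/AUC with Youden cutoffs, the Green sample-size formula — and a
synthetic-session generator with closed-form ground truth for testing.

## Worked example

Simulate a session with 40% unilateral weakness, 0.1 mm marker jitter and a
5° sinusoidal head wobble, then score it:

```sh
asfm3d simulate --severity 0.4 --noise-sd 0.1 --head-rotation 5 --seed 42 --out demo.trc
asfm3d score demo.trc --out report.json
```

The report contains (abridged):

```
D = 60.5   V = 94.2   A = 0   gross = 70.6
distance SR: brow 0.586, eye 0.595, pucker 0.602, smile 0.617, snarl 0.627
```

The distance ratios sit right at the generator's true attenuation
(1 − severity = 0.6); head motion is removed by the helmet frame. The speed
ratios are pulled toward 1 by jitter at this severity — peak-speed maxima
are far more noise-sensitive than peak-distance maxima at 30 Hz, which is
exactly why the composite weights distance 0.7 and speed only 0.3 (see
`docs/methods.md`). The resting face was built symmetric, so A = 0.

Prognosis from a second-visit SFGS of 55 and a gross score of 48:

```pycon
>>> from asfm3d import predict_month2, green_min_n, auc_class
>>> predict_month2(55.0, 48.0).raw
74.081
>>> green_min_n(0.673, 2)   # minimum n for a 2-predictor model at R² = 0.673
5
>>> auc_class(0.893)
'moderate'
```

A predicted final Sunnybrook score of 74 is above the good-recovery
threshold of 70. Packaged study cutoffs flag poor recovery when the gross
motion score is < 31 at the first visit or < 49 at the second
(`asfm3d predict --visit 1 ...` applies them to a cohort CSV).

## Caveats

The shipped resting-ratio reference intervals ([0.85, 1.18]) are
non-clinical placeholders; calibrate them on a healthy cohort before any
clinical use. The packaged prognostic coefficients and cutoffs are
study-derived constants, not re-derivable from this package alone. This
software is a research tool, not a medical device.
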