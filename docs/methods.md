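# Methods

## Pipeline model and assumptions

A capture session is a frame-indexed set of 3D marker positions (mm) at a
fixed frame rate (default 30 Hz): 21 facial landmarks — 8 bilateral pairs
(uppercase = subject's right by labeling convention, though all
paralyzed/contralateral logic resolves through the scheme plus a declared
side, never through case) and 5 midline points — plus ≥ 3 markers on a
rigid reference helmet. The session is segmented into one `rest` block and
the five standard expressions; segmentation is an input (half-open 0-based
frame intervals), not something the package detects.

Assumptions, in pipeline order:

1. **Helmet rigidity.** The helmet is rigidly fixed to the skull, so the
   per-frame least-squares rigid transform (Kabsch, no scaling, no
   reflection) mapping its markers onto their positions in a reference
   frame removes all head motion. The reference instant is the first
   rest-segment frame with all helmet markers visible. A per-frame helmet
   RMSD above 1.0 mm after alignment (configurable) logs a slippage
   warning. Frames with a missing helmet marker are flagged missing for all
   facial landmarks (policy configurable: flag / drop / error).
2. **Displacement origin.** A landmark's movement during an expression is
   measured from its rest baseline — the coordinate-wise mean over
   non-missing rest frames — rather than from the segment's first frame,
   which is sensitive to onset jitter.
3. **Kinematic maxima.** MMD is the maximum Euclidean distance from
   baseline; MMS and MMA are maxima of the velocity/acceleration vector
   norms (norm-of-vector, not along-path rate; the distinction is
   underdetermined by the score's definition and the norm is
   rotation-invariant). Missing frames are linearly interpolated for
   filtering but excluded from maxima.
4. **Symmetry ratios.** SR = paralyzed-side maximum / contralateral-side
   maximum per expression. The mouth corner contributes twice (smile and
   pucker), so D and V average five entries over four landmark pairs —
   mirroring the equal weighting of the five expressions in
   Sunnybrook-style composites. Both D and V are the mean SR × 100.
5. **Resting score.** Five right/left ratios (distances G–H, G–I, C–D,
   E–H; angle ∠CED) against per-parameter reference intervals; 4 points
   per abnormal pair.
6. **Composite.** raw = 0.7·D + 0.3·V − A; gross = raw clamped to
   [0, 100] (a complete palsy with all resting pairs abnormal gives
   raw = −20, which has no clinical meaning on a 0–100 scale); the raw
   value is always retained in reports.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| frame rate | 30 | Hz | capture hardware's rate; taken from file headers |
| smoothing window / order | 7 / 3 | frames / – | see below |
| SR cap | 1.0 | – | over-movement of the paralyzed side must not beat symmetry; capped entries are flagged, cap configurable |
| MMD noise floor | 0.5 | mm | below this, "motion" is marker noise: 0/0 → SR 1 (flagged degenerate); paralyzed-moves-while-reference-doesn't → error |
| resting reference intervals | [0.85, 1.18] all five | ratio | **placeholder** — the healthy-cohort values were never published; boundary values count as normal (deterministic tie-break) |
| helmet residual warning | 1.0 | mm RMSD | slippage guard |
| recovery thresholds | SFGS ≥ 70, H-B ≤ II | – | standard dichotomy; overridable in `RecoveryCriteria` |
| ROC bootstrap | 2000 resamples, stratified, seeded | – | assumption-light CI; DeLong not implemented |
| stepwise p-enter / p-remove | 0.05 / 0.10 | – | conventional defaults |

### Why a cubic smoothing fit

Velocity at 30 Hz is the fragile quantity in this pipeline. A quadratic
Savitzky–Golay fit over 7 frames attenuates the derivative of a 1 Hz
sinusoid by ≈ 5% at interior frames and overshoots by ≈ 12% at the
one-sided edge fits — a peak-speed bias of the same order as real
inter-side asymmetries. The cubic fit over the same window keeps the peak
speed of a 1 Hz, 5 mm sinusoid within 1% of 2πfA, remains exact on
polynomial trajectories up to degree 3, and costs higher noise gain
(15.4 vs 5.7 (mm/s)/mm per axis), which the jitter calibration below
absorbs. Segments shorter than the window fall back to central differences
with a logged warning; fewer than 3 frames is an error.

## The synthetic-session generator

`simulate_session` emulates what the reconstruction hardware hands the
pipeline: a nominal rest face (plausible geometry, not measured
anthropometry), 4 helmet markers in an asymmetric rigid tetrahedron, a rest
block then five expression blocks. Each expression displaces its analyzed
pair along a fixed direction with a raised-cosine bump
d(t) = (A/2)(1 − cos 2πt/T): zero endpoint velocity, peak displacement A,
peak speed πA/T — closed forms the generator exposes as ground truth so
tests never assert hand-derived constants. The paralyzed amplitude is
(1 − severity) × contralateral, so true distance and speed SRs are both
1 − severity. Requested resting right/left ratios are realized exactly by a
small constructive solve (G along I→G, H along G→H, E along H→E with C
carried rigidly, then D placed in the C/E/D plane to satisfy |CD| and ∠CED
simultaneously). Optional rigid sinusoidal head motion is applied to all
markers; Gaussian jitter is added last; everything is deterministic per
seed.

Default expression amplitudes (brow 8, eyelid 10, ala 6, mouth corner
12 mm) are physiologic plausibility values. The default jitter of
0.10 mm/axis is calibrated against the capture system's stated maximal
dynamic speed error of 5.8 mm/s: through the cubic derivative filter the
per-axis velocity noise is 0.10 × 15.4 ≈ 1.5 mm/s, and the empirical
perturbation of MMS stays ≤ 5.3 mm/s across 100 simulated expressions.

What the generator does **not** emulate: synkinesis, soft-tissue dynamics
and muscle physiology, marker occlusion/dropout patterns, helmet slippage,
reconstruction artifacts correlated across markers, or realistic facial
geometry. Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and its invariances (rigid-motion removal, side-exchange
symmetry, severity monotonicity), not clinical validity on real faces.

`simulate_cohort` draws clipped-normal predictors, applies a linear
prognostic model plus Gaussian noise, clamps the outcome to [0, 100] and
labels recovery. Because of the clamp, zero-noise coefficient recovery and
CI-coverage checks draw predictors from ranges where the model's outcome
stays inside [0, 100]; `noise_sd_for_r2` computes the residual SD for a
target R² from the realized signal variance.

## Numerical choices and degenerate inputs

* Rigid fits require ≥ 3 non-collinear correspondences; collinear
  configurations and reflections are rejected outright.
* 0/0 symmetry ratio → 1.0 with a `degenerate` flag (both sides immobile is
  symmetric); x/0 with x above the noise floor is an error, not an SR.
* An expression's degeneracy decision is made on MMD and applied to the
  speed ratio too, so one expression cannot be half-degenerate.
* Angle ∠CED is undefined (error) when C or D coincides with E.
* Youden-cutoff ties break toward higher specificity, then the smaller
  threshold; stepwise ties break by smaller p-value then name; a constant
  outcome selects nothing; duplicate predictors are skipped as
  rank-deficient, so exactly one of an identical pair can enter.
* Prognostic formula inputs are validated to [0, 100]; predictions are
  reported raw and clamped (the first-month intercept 132.112 exceeds the
  scale by construction).
* AUC below 0.5 classifies as "low" with an inverted-direction warning.

## Problem sizes in the test suite

Synthetic sessions are 11 s (330 frames) with 25 markers; regression and
ROC simulations use cohorts of 37 (matching the Green-formula check for a
2-predictor model at R² ≈ 0.67, n ≥ 5) with 100 seeded replicates for
coverage/selection rates; ROC–Mann-Whitney equivalence uses 100 instances
of n ≤ 20. The full suite runs in well under a minute on one CPU.

## Known limitations

* Stabilization is fit per frame from noisy helmet markers, so marker
  jitter leaks a small common-mode apparent velocity into all facial
  landmarks (lever-arm effect). At the default jitter this inflates speed
  ratios toward 1 at moderate severities — visible in the README example —
  while distance ratios are essentially unbiased. This mirrors the known
  instability of velocity measures at 30 Hz and is one reason the composite
  down-weights V.
* The resting reference intervals are placeholders (see above); abnormality
  flags under the default intervals are not clinically meaningful.
* Ratio-based resting abnormality is not exactly invariant under side
  exchange unless the interval is closed under inversion; with the default
  near-symmetric interval the asymmetry is second-order, and the
  side-exchange test exercises ratios where it cannot bite.
* The packaged prognostic coefficients, AUCs and cutoffs are constants from
  a 37-patient study; this package can apply them and can re-fit models on
  new data, but cannot re-derive them.
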