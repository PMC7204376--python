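# Methods

## Problem and model

Facial palsy impairs the motor function of one hemiface. During an eye
open/close task, the affected eyelid's excursion is reduced in proportion to
severity; the FNGS 2.0 eye score discretizes this into six bands, from
1 (normal) through "slight weakness, >75 % of normal", ">50 %", "<50 %",
"trace movement", to 6 (no movement). The package turns a 68-point landmark
sequence of the task into one scalar — the bilateral EAR difference — and
maps it back to an eye score.

### Amplified EAR

Per frame and per eye, the eye aspect ratio is the sum of the two vertical
lid distances over twice the horizontal corner distance. It is multiplied by
an amplification factor, the brow-reference-to-nose-tip distance over the
nose length (nasal root to tip). The rationale: the nasal root and tip are
nearly motionless during eye closure (displacements of a couple of pixels),
while the brow moves — and moves asymmetrically in palsy — so the factor
magnifies between-side differences without introducing scale dependence.
Both factors are ratios of distances, so EAR is invariant under translation,
rotation, and uniform scaling of the landmark set. Consequently no explicit
resampling into the normalization crop is performed for landmark-only input;
the crop geometry (box of width 2d centered on the eye midpoint C, extending
0.5d above and 1.5d below, with d the interocular distance) is used for
image cropping and for the detection sanity checks.

Tilt correction rotates each frame about C until the line through the two
eye-corner midpoints is horizontal. Only in-plane rotation is corrected; no
3-D pose estimation. Tilt correction is idempotent and makes the end-to-end
statistic invariant to any global in-plane rotation (verified to <1e-6).

"Left"/"right" are image-side labels throughout; mapping to anatomical side
is presentation-layer.

### Interocular distance

Defined as the distance between the two eye-contour centers (mean of the six
contour points each), not between outer corners. The center-based convention
is the common one for normalized landmark errors and, unlike corner- or
lid-based measures, is stable under eye closure.

### Bilateral asymmetry: discrete Fréchet distance

The left/right EAR series are treated as 1-D trajectory curves with time
encoded by sequence order. Their asymmetry is the discrete Fréchet distance
in the Eiter–Mannila coupling formulation: the minimum over monotone
couplings of the maximum pointwise gap, computed by dynamic programming over
the |P|×|Q| grid with cost |pᵢ−qⱼ|. An exhaustive path-enumeration oracle
(`frechet_naive`, guarded to |P|+|Q| ≤ 16) exists purely for verification;
the DP agrees with it to 1e-12 on random series. A literal per-index
maximum (identity coupling, equal lengths only) is exposed as
`coupling="identity"` for sensitivity analysis, since for per-frame-paired
curves of equal length the two readings can differ; the coupling-based
definition is the default because it is the canonical discrete Fréchet
distance. No temporal smoothing or resampling is applied by default.
The triangle inequality is deliberately not asserted as a property: it does
not hold in general for min-max couplings with this 1-D cost.

## Synthetic patients

Clinical image series are not distributable, so the generator is the
package's test bed. One "patient" is a single eye open/close cycle of
`n_frames = 30` frames (matching ~1 s at the 30 frames/s the landmark
pipeline sustains): the four lid points of each eye move toward the eye's
vertical midline by a raised-cosine fraction
A·(1−cos 2πt/n)/2 of the open height (A = `closure_amplitude`, default 1.0
= complete healthy-side closure). The affected side moves by the grade's
residual fraction of that; the defaults {1: 1.0, 2: 0.8, 3: 0.55, 4: 0.3,
5: 0.1, 6: 0.0} discretize the six verbal clinical bands and are fully
configurable (any non-increasing map with grade 1 → 1.0). Eye-corner points
stay fixed, keeping the EAR denominator stable as in real eye kinematics.
Each frame is then rotated in-plane by a uniform random angle bounded by
`head_sway_deg` (default 5°, emulating patient head sway) about the eye
midpoint, and every landmark receives isotropic Gaussian jitter of s.d.
`jitter_px` (default 0.3 px, a plausible annotation/detection noise floor).
Cohorts derive per-patient seeds from one base seed and randomize the
affected side; defaults are 15 patients per grade (90 total), comparable to
a single-site clinical cohort.

What the generator does **not** emulate: blink dynamics and multiple cycles,
out-of-plane pose, illumination, identity variation beyond similarity
transforms, synkinesis, and detector-correlated landmark errors. Passing
tests therefore demonstrate the correctness and internal consistency of the
measurement chain and its behavior under the modeled noise — not clinical
performance. In particular the synthetic cross-validation accuracy (~0.94)
and correlation (~0.985) are cleaner than values achievable on real
patients, because real grade classes overlap more than the discretized
residual-fraction bands do.

The renderer draws a deterministic grayscale face from any landmark set
(background gradient, skin fill from the jaw/forehead hull, dark brow and
eye polygons, nose shadow, mouth, Gaussian pixel noise; eye/skin contrast
≥ 30 gray levels so pixel-difference features are informative). It is a
deliberately schematic training substrate for the detector, not a
photorealistic synthesis.

## Cascaded regression-tree detector

Desk-scale re-implementation of cascaded shape regression with
gradient-boosted trees:

- **Initialization.** Mean shape (average of similarity-aligned training
  shapes) or another training shape, uniformly scaled and centered into the
  face box — the ground-truth bounding box padded 20 % and clipped to the
  image (no face detector is in scope; at inference the caller supplies the
  box or the whole image is used).
- **Features.** Per stage, a pool of pixel locations drawn uniformly over
  the mean-shape bounding box, each stored as (nearest landmark, offset).
  For a sample, offsets are mapped through the scale/rotation part of the
  least-squares similarity transform from the mean shape to the current
  shape and anchored at the current landmark — the standard shape-indexed
  construction that makes features pose-invariant. Node tests threshold the
  intensity difference of two pool pixels (nearest-pixel sampling, clipped
  at borders).
- **Boosting.** Residuals (target − current) are expressed in per-sample
  scale-normalized coordinates, dividing by the current shape's interocular
  distance fixed at stage start. Each depth-F tree greedily picks, per node,
  the best of `n_candidate_splits` random (pixel-pair, threshold) candidates
  by the usual sum-of-residuals gain; leaves store the shrinkage-scaled mean
  residual (least squares). Because each leaf update is ν·mean with
  ν ∈ (0, 1], the total squared normalized residual cannot increase, so the
  recorded per-tree training error (`train_history`, RMS normalized
  residual) is non-increasing within every stage by construction. Across
  stage boundaries the normalization scale is refreshed, which can move the
  recorded value by a sliver; monotonicity is therefore a within-stage
  guarantee.
- **Shrinkage.** The regularization parameter is implemented as GBDT
  shrinkage ν ∈ [0, 1]; ν = 0 makes the cascade an exact no-op. The
  hyperparameter grid search covers depths {2, 4, 5, 10} and shrinkage
  {0.001 … 0.9} by default and returns the test-NME argmin plus the full
  table.
- **Error metric.** NME = mean per-landmark Euclidean error divided by the
  truth's interocular distance (the standard, unsquared form); a
  squared-distance variant is available behind `squared=True` for
  sensitivity checks, but the unsquared form is the default because only it
  is normalized by a single power of the face scale.
- **Desk-scale defaults.** 5–6 stages × 40–50 trees of depth 4–5, feature
  pool 120–150, trained on ~60 rendered 96-px faces with 3 initializations
  each — sized so training completes in seconds while still more than
  halving the aligned-mean-shape baseline NME on held-out renders. All
  counts are configurable for larger runs.
- **Incorrect-detection flagging.** With ground truth: eye-subset
  (indices 36–47) NME above a threshold, default 0.08 — a documented,
  config-exposed choice. Without truth: geometric sanity checks (eye taller
  than wide, eye landmarks outside the normalization crop, self-intersecting
  contour — the last skipped for near-closed eyes, whose rings are
  legitimately degenerate).

Training-set augmentation applies seeded random similarity deformations
(rotation ≤12°, scale 0.92–1.08, translation ≤3 %) consistently to image
and shape, with the first copy an identity; default factor 10.

## Scoring and evaluation

FNGS 2.0 bookkeeping follows the published bands exactly (region scores 1–6,
secondary movement 0–3, grade bands I = 4, II = 5–9, III = 10–14,
IV = 15–19, V = 20–23, VI = 24; the maximal worksheet total of 27 falls in
the top band). Exclusion bookkeeping conserves per-score counts
(original = kept + excluded).

The eye-score classifier is intentionally minimal: one scalar feature, and
the nearest-class-median decision rule (ties toward the lower score), chosen
because per-score asymmetry intervals are well separated; interval-threshold
and 3-NN variants exist behind flags. Accuracy is exact six-class match.
Cross-validation uses a seeded uniform shuffle into k folds whose sizes
differ by at most one, unstratified by default (stratified variant behind a
flag). Pearson is the default correlation (per-sample, over non-excluded
subjects); Spearman is available.

## Numerical choices and degenerate inputs

- Degenerate geometry (coincident eye centers or corners, zero nose length)
  raises a dedicated error naming the frame.
- Landmark I/O is lossless to 6 decimals; sequences validate the 68-point
  schema, finiteness and strictly increasing frame indices on construction.
- Fréchet DP and oracle are compared at 1e-12; tilt-correction idempotence
  at 1e-9; end-to-end rotation invariance at 1e-6 (accumulated float error
  through rotation + correction).
- Classifier ties at exact midpoints resolve toward the lower score; the
  threshold variant's boundaries are half-open, so the two rules may differ
  exactly at a midpoint.
- Model serialization is a single `.npz` archive and round-trips to
  bit-identical predictions.

## Known limitations

- Only the eye region is modeled; brow/nose/mouth indices are out of scope.
- Only in-plane tilt is corrected; yaw/pitch would bias EAR on real images.
- The sinusoidal eyelid model and the residual-fraction discretization are
  assumptions, not fitted kinematics; synthetic results bound what the code
  can do under its own noise model, not clinical accuracy.
- The detector has no face detection and its renders are schematic; NME
  values on rendered faces are not comparable to benchmarks on photographs.
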