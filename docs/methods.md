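# Methods

This note records the models, parameter choices and known limits of
`presscope`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Savitzky–Golay trend filter

The filter is built from its least-squares definition. For a symmetric
window of 2M+1 samples at abscissae n = −M…M and polynomial degree k,
the design matrix A = [nⁱ] (i = 0…k) gives the projection
P = A(AᵀA)⁻¹Aᵀ; the centre row of P is the smoothing impulse response,
and the off-centre rows evaluate the window's fitted polynomial at the
off-centre positions, which is how the `interp` boundary mode handles
signal edges. Implementation solves the normal equations rather than
forming an inverse; validity requires 0 ≤ k ≤ 2M. Two identities are
used as test anchors: the weights sum to one (degree-0 reproduction) and
odd-degree weights equal the next-lower even degree (the odd basis term
is orthogonal to centre evaluation on a symmetric window).

## External-object removal

Per line, `S′ = |f(S) − avg(f(S))|` and sensels with `S′ > th` keep
their raw value. Three numerical choices matter, all fixed after
design-phase experiments on the synthetic phantom and then left alone:

* **Averaging scope.** `avg(f(S))` is taken over the whole frame's
  smoothed lines (`mean_scope="global"`), not per line. A pressure map
  is mostly empty mat, so the global average sits at the empty-bed
  baseline and body mounds stand far above it. A per-line average on a
  body-bearing column sits mid-trend (the column carries head, sacrum
  and heels end to end), which pins `S′` near zero over real body signal
  — the rule then cannot retain the body. Per-line averaging remains
  available (`mean_scope="line"`).
* **Window size.** The base rule M = r/2, with r = 32 sensels across the
  bed, sizes the window to one transverse line of the row-major unfolded
  signal. Processing per column (the default; columns are the long,
  head-to-foot axis), a 33-tap window spans half the 64-sample line and
  merges neighbouring body mounds into one plateau, erasing the trend
  contrast. The window adjustment ε (a free tuning parameter of the
  rule) defaults to −8, i.e. M = 8, a 17-tap window at the scale of one
  body mound. ε is exposed for scenes with unusual object load.
* **Boundary handling.** The removal path uses reflect-padding. With
  polynomial edge evaluation, everything within M samples of a line end
  is an extrapolation zone; the head (row ~5) and heels (row ~59) live
  there, and a single edge polynomial flattens their bumps (deviation
  ~1.5 mmHg instead of ~14), so they would be deleted as "object".
  `sg_smooth` itself defaults to polynomial edges (`interp`), the
  standard choice for generic smoothing.

The retention threshold comes from the supervised grid search
(maximizing the F1 of the retained mask against the ground-truth body
mask; ties go to the smaller threshold, which retains more body). On the
default calibration scenes the search returns 14 mmHg; the fixed
fallback default is 12 mmHg. For object-free data a noise-floor
threshold (2 × robust σ of the background deviation field, ≈2 mmHg at
the default noise level) leaves the body essentially untouched —
cleaning is then a no-op up to sensor noise.

**Idempotence caveat.** Re-cleaning a cleaned frame never reintroduces
signal: values are unchanged on the retained support and the nonzero
support only shrinks. The boolean deviation mask itself can flip on a
handful (≈0.1–0.4%) of already-zeroed sensels, because removing mass
lowers the global average and sharpens mound edges, raising `S′` just
outside them; those sensels hold zeros, so the flip has no effect on the
signal. This is a property of the deviation rule, not of any particular
averaging scope or degree.

## Metrics

RMSE is computed on frames normalized by the sensor range (1000 mmHg).
PSNR is `20·log₁₀(peak/RMSE)` with `peak` the maximum of the normalized
reference frame; the conventional MAX = 1 form is inconsistent with
published PSNR/RMSE pairings for this kind of data, while the
frame-peak form reproduces them (e.g. peak 0.655 with RMSE 0.102 gives
16.15 dB). Identical frames return +∞.

## Synthetic scenes

The generator emulates a 64×32 mat at 1 Hz. The body is a sum of
squared-exponential bumps at the high-risk prominences; defaults
(supine): head (row 0.08R, peak 50 mmHg, σ 2.2), shoulders (0.22R,
±5.5 columns, 55 mmHg, σ 2.8), sacrum (0.55R, 65 mmHg, σ_r 4 × σ_c 3.5),
heels (0.92R, ±5 columns, 85 mmHg, σ 2). Lateral postures shift the body
axis by ±4 columns, drop the contralateral shoulder and foot, raise the
shoulder/hip peaks (65/70 mmHg — side-lying loads are more focal) and
put the single shoulder at 0.25R. Magnitudes follow published interface
pressure ranges for adults on standard foam (peaks ~40–90 mmHg; heels
and the lateral trochanter at the high end). Sensor noise is additive
Gaussian, default sd 5 mmHg, clipped with the sum to [0, 1000].

The default external object is a lateral positioning cushion (rows
0.30–0.75R, columns 1–8, relief 7 mmHg, 2-sensel edge taper): a broad
foam aid bearing light load, placed beside the trunk. An under-leg wedge
generator is also provided; objects that share columns with strong body
signal are only partially removable, because the method requires the
body to dominate the line trend — this is the approach's documented
operating condition, and scenes violating it are expected to degrade.

Ground truth records the noise-free body and object layers, a body
contact mask at ≥ 20 mmHg (interface pressures of clinical concern), an
object footprint mask at half the object's relief, the landmark table
and the posture label.

What the generator does **not** emulate: contiguous full-body
silhouettes (real torsos load the mat between the prominences),
posture transitions and motion, bed inclination, sensor calibration
drift and dead sensels, and between-subject variation beyond the
jittered landmark geometry. Passing tests therefore demonstrate the
pipeline's correctness under the stated model of body-vs-object trend
contrast, not clinical performance on real recordings.

`labelled_dataset` adds subject structure: each synthetic subject draws
one morphology (axis shift ±2 columns; per-landmark position ±1.5
sensels, peak ±10%, spread ±15%) applied consistently across postures,
with fresh sensor noise per frame. Zero jitter makes same-class frames
identical — jitter and noise are the only randomness.

## Posture classification

Enhancement chain (SG-2D degree 2 window 7, then Gaussian σ 1.4) →
bicubic ×4 upsampling → HOG (8 orientations, 8×8 cells, 2×2 blocks, L2
block norm; 14 880 features for a 64×32 frame). The "window size 6" SG
variant reported for this filter family is even and cannot form a
symmetric window; it is normalized to 7 (M = 3). SVM uses an RBF kernel
on standardized features; KNN (k = 10) runs on the raw HOG vector —
blocks are already contrast-normalized, and standardizing the many
near-constant dimensions lets noise dominate the distances; the random
forest uses 100 trees. The split is subject-wise (20% of subjects held
out) and cross-validation is grouped by subject, 10 folds or one per
training subject when fewer (with a warning). The sacrum-only scope
crops rows [0.45R, 0.65R) before feature extraction.

## Region detection, labelling, tracking

Gradient by central differences (one-sided at borders). A sensel is a
candidate maximum when the row gradient changes + → − down its column
and the column gradient changes + → − across its row; candidate
components that do not rise above their 8-neighbourhood ring (flat
plateaus, saddles, whole-frame constants) are discarded, surviving
plateaus resolve to their centroid. Regions grow by 4-connected flood
fill at 0.65 × the seed value; 0.5 (the half-maximum disc) lets the
blurred tails of close landmark pairs (lateral head/shoulder, the two
heels) bridge and merge, which defeats per-landmark labelling. Cleanup:
3×3 morphological opening, minimum area 4 sensels, and a plausibility
filter on the centroid row against the posture template bands (head
< 0.18R, shoulders 0.15–0.35R, sacrum 0.40–0.70R, feet > 0.80R) —
hand/elbow-sized specks and mid-lateral decoys are removed. Labelling is
purely spatial; left/right are image-frame. Mean pressures are always
computed on the raw frame so tracked values stay in physical mmHg.
Track association uses a 5-sensel/frame centroid gate — monitored
patients barely move; frames where a label is missing or outside the
gate are recorded as gaps.

## Problem sizes

The validation suite uses the study's own scales chosen for a desk-class
machine: 200 random signals across (k, M) ∈ {2,3} × {2,4,8,16} for the
SG oracle; 50 cushion scenes plus 20 object-free scenes for removal; 200
frames/class over 10 subjects for the classifier benchmark; 100 scenes
for landmark recovery; 120 frames for tracking. `scripts/acceptance.py`
re-runs the same study (classifier at 150 frames/class) end to end in a
few minutes.

## Known limitations

* Object removal assumes the body dominates each line's trend; many or
  heavy objects, or objects under the body's own columns, break the
  assumption and survive partially.
* The supine body must present separated pressure mounds; a uniformly
  loaded silhouette (very soft mat, heavy bedding) reduces trend
  contrast and body retention.
* Labelling assumes a roughly bed-aligned, non-inclined posture; prone
  lying and bed inclination are out of scope.
* The classifier benchmark is synthetic; accuracy on real mats depends
  on sensor noise structure and population variability not modelled
  here.
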