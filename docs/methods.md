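# Methods

## The problem

Micro-expressions (MEs) are involuntary facial movements lasting a fraction
of a second (1/15–1/25 s) with sub-pixel to few-pixel amplitude. Analyzing
them in high-speed video involves two tasks: **spotting** — which frames
contain an ME, and where its apex (peak) frame is — and **recognition** —
which of the three pooled emotion classes (positive, negative, surprise) the
movement expresses. `microexp` implements both from one cheap primitive: the
normalized frame-difference *motion-magnitude image*.

## Face geometry

A 68-point landmark set (iBUG ordering) positions 10 axis-aligned square
cells that roughly cover the territories of the facial-expression muscles:
left/right frontalis and procerus above the brows, the two orbicularis oculi,
two zygomatic-region cells lateral to the nose wings, the two mouth corners,
and the mentalis on the chin. The shared cell side is half the mouth width
(distance between landmarks 49 and 55). In-plane rotation is removed first:
the roll angle is the inclination of the line joining the outer eye corners
(landmarks 37 and 46), and image plus landmarks are rotated about the
landmark centroid so that it becomes 0 (bilinear resampling, zero fill).
Yaw and pitch are not corrected; the method targets frontal recordings.

Cell anchors (mid-brow points, eye centroids, nose wings, mouth corners,
below-lip point) and their offsets (0.6 side above the brows, 0.75 side
outward/downward for the nose-wing and chin cells) are exposed in
`CellLayout`. Cells are clipped to the image at use time; a cell entirely
outside the frame is an error. Pixel bounds round half-up, so the mapping
from real-valued centers to pixel sets is deterministic.

## Motion descriptors

For frame *t*, with `tau` the average ME duration in frames (65 at 200 fps,
37 at ~100 fps; default 37) and `eps` a short lag (default 3 frames):

    MM_t(x, y) = (|f_t - f_{t - tau//2}| + 1) / (|f_t - f_{t - eps}| + 1)

The numerator measures displacement since a potential onset half an ME back;
the denominator measures change over a span too short for facial motion and
so normalizes out sensor noise and flicker. Both `+1` regularizers act on the
native 0–255 intensity scale. Reference indices clamp to frame 0. On a
static scene MM ≡ 1; it is strictly positive and invariant to global
intensity offsets.

Two derived quantities drive everything else:

* **Cell signal** µ_c(MM_t): the mean of MM over cell *c*. The first
  ceil(tau/2) frames have no onset reference and are stored as 0.
* **Weighted centroid** of MM inside a cell (intensity-weighted mean pixel
  position). Its drift across a window of size `tau` centered on the apex,
  resampled to `n_resample` = 11 frames (rounding half-up, no temporal
  interpolation) and differenced against the window's first frame, gives the
  per-cell displacement feature — 10 cells × 10 (dx, dy) pairs.

Two properties of this descriptor matter for interpreting results, and are
asserted in the tests because they are easy to get wrong:

* The cell signal does **not** peak at the apex in general. It peaks where
  the current frame is quiet (small short-lag difference) while the half-tau
  reference still straddles large displacement — for an event that releases
  quickly, that is between the apex and apex + tau/2 (+eps for step-like
  changes).
* The centroid displacement of a feature that translates by Δ reports
  roughly Δ/2 (the difference pattern forms lobes at the old and new
  positions; the centroid sits midway), scaled by the pattern's share of the
  cell's MM mass. Mid-release frames are unreliable: there the short-lag
  denominator is itself dominated by the motion and can invert the pattern.
  Apex-adjacent frames, where motion stalls, are the clean probes.

## Spotting

Each frame is described by 20 numbers: per cell, the minimum and maximum of
µ_c over the window [t − tau//2, t + tau//2] (clamped at the borders; the
sliding implementation uses min/max filters with edge replication, which is
exactly window clamping). Ground-truth labeling marks frame *t* as ME iff
|t − apex| < delta·tau (strict, real-valued; delta = 0.25). The heavily
unbalanced training set is balanced by keeping all ME frames and sampling an
equal number of non-ME frames without replacement.

The classifier is discrete AdaBoost (SAMME) over 35 depth-limited decision
trees. The default tree depth is 2: the ME-frame signature under windowed
min/max features is a *conjunction* (window max elevated while the window
min still reaches the pre-onset baseline, jointly across cells), which a
depth-1 stump cannot represent — with stumps, leave-one-subject-out
detection degrades to roughly half. Depth is configurable.

Raw per-frame labels are post-processed: maximal ME runs are extracted; runs
whose gap is < `max_dist` (default 2·tau) are merged to a fixpoint; runs
shorter than `min_micro_sz` (default tau//4, length measured as end − start)
are dropped; each survivor's apex is its middle frame. The merge condition
is the gap between clusters; the alternative reading that compares run
*lengths* is available as `merge_rule="printed"` for fidelity experiments.

Spotting is scored per event: greedy nearest-first one-to-one matching
between detected and ground-truth apexes; a match requires
|apex_gt − apex_d| ≤ delta·tau (non-strict). The false-positive rate is
unmatched detections divided by the number of ground-truth MEs.

## Recognition

Training pools the displacement pairs of all training sequences per class
and per cell and fits a bivariate Gaussian to each pool: sample mean,
unbiased sample covariance plus a floor of 1e-6 px² times the identity
(guaranteeing positive-definiteness even for degenerate pools; an
alternative `pooling="mean"` mode averages each sequence's pairs into a
single observation first). A sequence is classified by summing the standard
bivariate normal log-densities of its observations under each class model
across cells and taking the argmax; ties break on the fixed order
positive < negative < surprise. Log-densities are computed via Cholesky
factorization. A monotone common factor in the density normalization cannot
change the argmax, so the standard normalization is used throughout.

Recognition training always uses annotated apexes. At test time the apex
source is configurable: annotated apexes (the default, matching how
recognition accuracy is conventionally reported on annotated clips) or the
apexes produced by the spotter (the fully automatic path,
`apex_source="detected"`).

## Synthetic face videos

The generator exists so every stage is trainable and testable without
licensed datasets. A scene is: a smooth Gaussian-filtered random skin field
(sigma 3 px, std 12 intensity units) anchored to a built-in 68-point frontal
template; darker blobs (amp 25, sigma 2) at brow/eye/outer-lip landmarks;
and one localized "muscle feature" blob per cell (amp 60, sigma 3), resting
at the pixel-grid centroid of the clipped cell. An expression event moves
the muscle features of its class's cells along class-specific unit
directions (FACS-guided: surprise raises brow and eye cells; positive pulls
mouth corners and zygomatic cells outward/upward; negative knits the brows
down/inward, depresses the mouth corners and raises the mentalis) with a
piecewise-cosine onset→apex→offset envelope, rendered at sub-pixel positions
over the static skin and clipped to the cell's pixel window. Per-pixel
Gaussian noise (default sigma 2 on the 0–255 scale) and an optional global
multiplicative flicker are added, and frames are quantized to integers like
an 8-bit sensor.

Design choices worth stating explicitly:

* **Moving feature over static skin, not rigid texture translation.** A
  rigid translation of spatially stationary texture produces a
  gradient-magnitude difference pattern whose *shape* is fixed — only its
  amplitude changes — so the MM centroid cannot drift along the motion
  direction and direction recovery is impossible in principle. A localized
  feature sliding over skin (a brow edge, a mouth corner) is the physical
  situation in which the centroid statistic carries direction, and is what
  the generator renders. Anchoring the feature at the pixel-grid centroid of
  the cell makes the rest centroid coincide with the uniform-MM centroid, so
  measured displacements are pure motion.
* **Event shape.** Durations are drawn from U[28, 44] frames (mean ≈ tau =
  37, consistent with tau being the *average* ME duration at 100 fps) and
  the apex sits at U(0.78, 0.88) of the duration: a slow build-up with a
  fast release. Besides being a recognized asymmetry of spontaneous
  expressions, this places the apex at the center of the region where the
  descriptor responds ([onset, offset + tau/2]), so the middle-of-interval
  apex estimate of the post-processing stage is approximately unbiased. With
  a symmetric envelope the estimate is biased late by roughly tau/4 and
  spotting scores collapse — a descriptor property, not a code artifact.
* **Dataset layout.** Default 8 subjects × 5 sequences of 260 frames at
  100 fps; per subject a fresh texture seed and 0.8 px Gaussian landmark
  jitter; 0/1/2 events per sequence with probabilities (0.2, 0.6, 0.2);
  classes uniform; magnitudes U[1, 4] px (experiments below use 2–4);
  consecutive events are separated by > 2·tau frames so the merge stage
  cannot fuse them. Everything is a pure function of (parameters, seed).

What the generator does **not** emulate: head pose changes, blinks,
macro-expressions, illumination gradients, skin deformation (stretching and
shearing rather than translation), and landmark detector error beyond static
jitter. Passing tests therefore demonstrate that the pipeline recovers the
events its own model family describes under realistic noise — not
performance on any real recording.

## Evaluation protocol

`evaluate` runs leave-one-subject-out cross-validation: per fold, the
spotter (balanced training, fold-specific seed spawned from the master seed)
and the recognizer are trained on all other subjects and applied to the
held-out subject; sequences shorter than tau are skipped with a warning.
The report aggregates: the per-frame ME/non-ME confusion both before and
after interval post-processing; event-level detection rate and
false-positive rate (overall and per class); and the 3-class recognition
confusion with accuracy and macro precision/recall/F1. Percentages print
with 2 decimals, half-up. Reports are bitwise reproducible given the seed.

On the synthetic study conditions (8×5, tau 37, magnitudes 2–4 px, noise
sigma 2) the pipeline typically reaches a detection rate of 0.80–0.90 with a
false-positive rate below 0.10 and recognition accuracy above 0.90; with
noise off and magnitudes 4–6 px both detection and recognition exceed 0.95
(pooled over replicates — single 33-event draws fluctuate by one event, i.e.
±3%). Permuting event labels drives recognition to the 1/3 chance band.
These numbers are recomputed, not quoted: `scripts/acceptance.py` and
`tests/test_acceptance.py` produce them at run time.

## Numerical conventions

* Rounding of real-valued positions to pixels and of resampling positions to
  frame indices is half-up (`floor(x + 0.5)`), never banker's rounding.
* Window clamping at sequence borders is exact (filters use edge
  replication, equivalent to intersecting the window with the sequence).
* Covariances are floored at 1e-6 px² · I; log-densities use Cholesky
  factorization and raise on non-positive-definite input.
* All randomness flows from `numpy.random.default_rng` / `SeedSequence`
  spawning; derived seeds stay below 2^31.

## Known limitations

* The per-frame classifier keys on absolute signal levels; depth-2 trees can
  carve training-range intervals and occasionally reject an out-of-range
  (unusually strong or weak) event of an unseen subject outright.
* The apex estimate is the middle of the merged interval; its accuracy
  depends on the event's release being faster than its build-up. Events that
  decay slowly bias the estimate late.
* Sequences shorter than tau cannot be processed at all (no onset
  reference) and are skipped.
* Only roll is normalized; out-of-plane head rotation violates the cell
  geometry and is out of scope.
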