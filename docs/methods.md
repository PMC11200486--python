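# Methods

This note records the models, conventions and numerical choices behind
omgeye, and what the synthetic tests do and do not establish about real
data.

## Data model and conventions

A `LabelMask` is a row-major, 0-based grid of class ids
{0 skin, 1 pupil, 2 iris, 3 sclera, 4 caruncle}; the on-disk form is a
palette PNG with the fixed color code skin (0,0,0), pupil (0,255,0),
iris (255,0,0), sclera (0,0,255), caruncle (255,255,0).  Decoding is
exact-match only: an off-palette pixel raises an error naming the RGB
value and location, because silently snapping label noise to the nearest
class would corrupt ground truth without a trace.  A `ProbMap` holds
per-pixel class probabilities (sum 1 within 1e-6); `argmax` ties break to
the lowest class id so evaluation is reproducible.  Rectangles are
half-open; eye-crop boxes are padded by 25% of each side by default and
clipped to the image.

## Losses

Cross entropy and weighted cross entropy are means over pixels;
probabilities are clipped to [1e-7, 1] inside logarithms to keep the loss
finite under hard wrong predictions.  Weighted CE interprets its weights
per class; the default weights are inverse class frequencies in the
ground truth, normalized to mean 1, so the tiny pupil and caruncle are
not drowned out by skin.  Soft IoU and Dice average per-class overlap
ratios; a class absent from both prediction and ground truth contributes
a perfect ratio of 1 (no penalty for something that is not there).  The
same convention is used everywhere a 0/0 ratio can occur, including the
evaluation metrics, so losses and metrics never disagree about degenerate
classes.

**Boundary band.**  A boundary pixel is one with a 4-neighbor of a
different class; the image frame is not a boundary (a uniform mask has
none).  The band of half-width `d` is every pixel within Euclidean
distance `d` of a boundary pixel, computed with a distance transform.
`d` comes from the image size as `max(1, round_half_up(0.02 × diagonal))`.

**Boundary loss.**  Soft IoU restricted to the union of the ground-truth
band and the band of the argmaxed prediction, averaged over the four
ocular classes (pupil, iris, sclera, caruncle) — the skin boundary is
exactly the union of theirs, so including skin would double-count.  Using
the union of both bands makes the loss symmetric under swapping hard
predictions with labels; with `d` at least the image diagonal the band
saturates and the loss collapses to soft IoU over the same classes.  An
image with no boundaries at all scores 0.

**Hybrid loss.**  `α·global + β·local + γ(e)·boundary` with α = β = 1 by
default and γ ramping linearly from 0 at the first epoch to `γ_max` at
the last (the ramp shape is a design choice; linear is the simplest
monotone option and evaluated once per epoch).  The boundary term thus
only dominates once the global/local terms have formed a coherent
segmentation — the point of scheduling it at all.

## Metrics

Per-class IoU, Dice, precision, recall and F1 from pixel confusion
counts.  F1 is computed from counts (`2tp / (2tp+fp+fn)`) rather than
from precision and recall, so the 0/0 → 1 convention is applied once and
the per-class F1 = Dice identity is exact.  Area metrics average over all
five classes by default; MBIOU (hard IoU on band pixels only) averages
over the four ocular classes, mirroring the boundary loss.  Both class
sets are caller-configurable.  Timing helpers report mean wall time and
are never part of any assertion — they are hardware-dependent.

## Ocular indicators

The pipeline is: regularize the mask → fit the iris → measure.

**Regularization.**  The pupil and iris are physiologically
quasi-circular, so their segmented regions are replaced by fitted
rasters.  Region contours are extracted at the 0.5 iso-level (subpixel,
via marching squares); contour stretches adjacent to skin are excluded
from fitting, because where the lids clip the iris the region boundary
follows the lid margin, not the limbus, and would flatten the fit.  The
pupil is fitted as a general ellipse (direct least-squares conic fit;
points are centered and scaled first for conditioning — exact-data
recovery is at machine precision).  The iris structure (pupil∪iris
region) is fitted as a **circle** (algebraic Kåsa initialization refined
by geometric least squares): when only a partial limbus arc is visible —
a drooping lid, or the iris parked at the fissure corner in lateral gaze
— a general ellipse is badly underconstrained by a single arc, while a
circle remains stable, and a front-view iris is a circle to very good
approximation.  Fitted rasters are clipped to the original fissure (the
lids keep covering what they covered; completing the circle over lid skin
would corrupt the lid-derived indicators), with overwrite priority
pupil > iris; former pupil/iris pixels left uncovered become sclera.  An
empty region or failed fit passes through unchanged.

**Eyelid distance** is the maximum per-column vertical extent of the
fissure (pupil∪iris∪sclera).  The caruncle is excluded from the fissure —
it sits in the canthus, not between the lids — but included in the eye
area, which it is anatomically part of.

**Clock point.**  The fitted iris is read as a circle of radius `r` (the
major semi-axis) centered at `(cx, cy)`.  The upper-lid margin height `h`
is the topmost fissure row in the column nearest `cx`; the relative drop
`t = (h − (cy − r)) / 2r`, clamped to [0, 1], is mapped to hour bands via
the chord heights of hour lines placed every 30° on the clock face:
thresholds `(1−cos30°)/2, (1−cos60°)/2, 1/2, (1+cos60°)/2, (1+cos30°)/2`
for bands 12, 11–1, 10–2, 9–3, 8–4, then 7–5, and 6 at `t = 1`.  Exact
threshold values are written as algebraic constants (`cos60° = 0.5`, not
`math.cos(pi/3)` which is 1 ulp high) so the documented tie rule — a
boundary value goes to the *less severe* band — behaves exactly.  Grades:
12 and 11–1 → 0, 10–2 → 1, 9–3 → 2, 8–4 → 3, 7–5 and 6 → 4.  The grade
is monotone in `t` by construction.  A closed eye (or unfittable iris)
reports band 6, grade 4.

**Scleral area.**  Sclera pixels are split by the vertical line through
the iris center: strictly left / strictly right, with pixels exactly on
the line assigned to neither — this keeps the split exactly equivariant
under horizontal flips.  The gaze side ("left"/"right", supplied by the
caller; "front" falls back to the larger side) selects the count whose
ratio to the eye area (pupil∪iris∪sclera∪caruncle) is the scleral
proportion.

## Screening rule

An eye is flagged OMG when its gaze-side scleral proportion strictly
exceeds 3%; equality is read as normal (the conservative reading of a
strict-inequality rule).  Two eyes combine by OR.  Clock grade and eyelid
distance appear in the report as supporting evidence but do not enter the
decision — the rule is deliberately a single-indicator screen.

## Synthetic eye generator

The generator emulates the geometry the indicators measure, not eye
photographs.  The palpebral fissure is bounded by two parabolic lid arcs
with maximal separation `aperture` (the arcs themselves belong to the
lids: zero aperture yields no fissure); the fissure half-width is twice
the iris radius; `lid_curvature` skews the aperture split between upper
and lower arc.  Inside the fissure sit the iris disk — shifted from the
fissure center by `gaze_offset` — and the concentric pupil disk; the rest
is sclera except a caruncle wedge (fissure pixels beyond |u| = 0.85 on
the nasal side, ≈2–3% of the eye area).  Default dimensions (192×144 px,
iris radius 32 px) are typical of a cropped eye patch at the resolution
segmentation models consume.

Ground-truth indicators are computed at generation time by exact pixel
counting against the *true* generating circle — no fitting — so
generator/analyzer closure tests compare the pipeline against an
independent geometric oracle.  Because the reference is the rasterized
mask, the documented tolerances are ±1 px on eyelid distance and ±0.01 on
the proportion; the clock grade is exact except when the true lid drop
lies within fit noise (≈0.005 in `t`) of a band threshold, where no
estimator can decide the band with certainty (observed: 99–100 agreement
per 100 random eyes).

`corrupt_prediction` emulates imperfect network output: pixels within
`jitter_px` of a boundary take the label of a random pixel up to
`jitter_px` away, then the one-hot encoding is blended with the uniform
distribution by `softness`.  Cohort generation draws per-subject
geometry, then scans the gaze offset deterministically until the
ground-truth proportion realizes the phenotype (normal < 2.5%,
affected ≥ 3.5% — both a safety margin away from the 3% rule).

What passing these tests does **not** show: robustness to real
segmentation-network errors (anatomically correlated, not iid jitter),
to non-frontal head pose, to caruncle/sclera confusion in low light, or
to eyes whose iris is genuinely elliptical in projection (strong lateral
gaze with perspective).  The generator's lids are parabolic and its gaze
shift purely horizontal; none of the clinical variability of lid shape is
modelled.

## Stability experiment

A deliberately tiny experiment reproduces the qualitative finding that a
boundary loss destabilizes training unless a global loss anchors it.  A
one-hidden-layer MLP (16 tanh units, ~200 parameters) classifies pixels
of 64×64 synthetic eyes from hand-crafted features (intensity at three
blur scales, gradient magnitude, normalized position); 16 training and 6
held-out eyes.  Per step, a random 25% pixel subsample of one image is
used for the gradient — the stochasticity ordinary mini-batching has —
while the loss curve records the full-image value, so curve jitter
reflects parameter dynamics, not measurement noise.  The optimizer is
Adam (lr 0.03): with plain SGD the ratio-form losses' raw gradients are
so small that Dice-mode training freezes in a degenerate solution and the
phenomenon is invisible; Adam's per-parameter normalization both lets
ratio losses train and converts their gradient noise into full-sized,
oscillation-prone steps — as in real segmentation training.  All modes
share seed, initial weights, data, subsamples and γ ramp; only the loss
composition differs.  The oscillation index of a curve is
mean |Δloss| / (range + 1e-12): 0 for constant, 1/(k−1) for monotone,
→1 for alternating.  The experiment claims only the *ordering* across
modes (L+B oscillates more than G+B and generalizes worse); absolute
values are meaningless at this scale.  Problem sizes (16 eyes, 64×64, 24
epochs, 10 seeds) keep a full repetition set around half a minute on one
CPU core.

## Known limitations

- Pixel units throughout; no mm calibration, so indicators are not
  directly comparable across imaging distances.
- Gaze direction must be supplied; the package does not estimate it.
- The clock-band geometry (30° hour lines on the fitted circle) is this
  package's operationalization of the clinical grading; other readings of
  "the lid reaches N o'clock" are possible.
- The screening rule is single-indicator by design; combining clock grade
  and eyelid distance into the decision is future work.
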