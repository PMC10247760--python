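# Methods

`hipscreen` models a point-of-care screening workflow for developmental
dysplasia of the hip (DDH): a lightly trained operator sweeps an ultrasound
probe across an infant's hip in the coronal plane, software segments the
anatomic landmarks in each frame, measures the Graf indices, gates frames on
landmark adequacy, and returns one of three management calls — *Healthy*,
*FU Recommended*, or *Inconclusive, Repeat Scan*.  Because no clinical hip
ultrasound data ship with the package, every stage runs against a synthetic
phantom whose geometry is known exactly; the phantom is therefore first-class
code, not a test convenience.

## Coordinate and label conventions

All modules share one convention, fixed by the phantom: 0-based `(row, col)`
pixel indices with the origin top-left; the iliac baseline runs approximately
parallel to the image vertical (row) axis as in a standard Graf-orientation
view; the medial (covered) side of the joint is toward increasing column.
Label masks use `0` background, `1` acetabulum–ilium complex, `2` femoral
head.  For arbitrary external input the medial direction is a declared
configuration, not an inference.

## Phantom model (`hipscreen.phantom`)

A frame is assembled from analytic primitives on a mid-gray background
(level 0.35):

* a bright (0.95) iliac stroke of half-width 1.5 px ending at the bony rim;
* a bright acetabular-roof stroke leaving the rim medially at exactly the
  true alpha angle;
* a hypoechoic disk (0.08) for the femoral head.  Its column offset from the
  baseline fixes the true coverage through the diameter-fraction identity
  `fhc = clip((r + s) / 2r, 0, 1)`, where `s` is the signed medial distance
  of the center from the baseline.  Its row is chosen so the disk nestles
  just below the roof line without touching the bone stroke, which keeps the
  rasterized landmark classes disjoint and circle fits unbiased.

Texture is layered on top in this order: unit-mean multiplicative gamma
speckle with variance `speckle_strength`, Gaussian blur of `blur_sigma_px`,
and acoustic shadowing (intensity attenuation of up to 60 % ×
`shadow_strength` below any bone echo in the same column).  Default
difficulty — speckle 0.03, blur 0.8 px, shadow 0.2 — was chosen once as a
plausibly mild point-of-care texture and is used everywhere a "low-noise"
cohort is called for; "noise-free" phantoms set all three to zero.

Out-of-plane behaviour is driven by a scalar `plane_offset` and an adequate
band (default half-width 16 px).  Inside the band the frame is fully
rendered.  Beyond it, bone echoes fade and shorten linearly over one band
width and the head loses contrast twice as fast, emulating how landmarks
drop out when the probe leaves the standard plane.  The truth mask applies a
crisp version of the same rule — the head class is present iff the frame is
within the band; bone strokes truncate progressively — so adequacy gating
has an exact reference while image intensities stay continuous.

What the phantom does **not** model: wave propagation or scatterer physics,
3-D anatomy, probe motion beyond the scalar offset, soft-tissue layers, the
labrum, or any appearance statistics of real clinical frames.  Tests passing
on phantoms therefore demonstrate the correctness of the measurement and
decision machinery, not clinical segmentation performance.

## Segmentation (`hipscreen.segmentation`)

**Preprocessing.** Frames are divided by their overall mean intensity
(output mean exactly 1 before resampling) and bilinearly resized to a square
model input; masks resize by nearest neighbour so labels stay integral.
"Normalize by overall average pixel intensity" admits several readings; the
plain division was chosen and is isolated in `preprocess` so it can be
swapped.

**Network.** A U-Net-style encoder–decoder implemented directly in NumPy
(`segmentation.nn`): double 3×3 conv + ReLU per level, 2×2 max pooling,
nearest-neighbour upsampling with skip concatenation, Xavier-uniform
initialization.  The default scale (depth 3, 8 base channels, ~20 k
parameters) trains on one CPU core in a few minutes; depth and width are
configuration.  The output head emits **one sigmoid logit map per foreground
class** rather than one softmax over three classes: with a softmax, the
gradient of the batch-aggregated DICE loss lets an easy large class (the
head disk) crush the very thin bone class into saturation during the first
epochs, after which the thin class's gradient — proportional to its
probability — vanishes.  Independent per-class sigmoid heads decouple the
two problems and train stably; head biases are initialized to the class
log-odds priors of the training masks, which keeps the thin-class
denominator small at the start.  For inference the background score is
composed as the product of the foreground complements and the triple is
normalized, so `segment` still returns per-pixel probabilities that sum to
one.

**Loss and model selection.** The loss is soft DICE over the foreground
classes, aggregated over the batch, with smoothing constant ε = 1 px to
guard empty classes: `1 − mean_c (2Σst + ε)/(Σs + Σt + ε)`.  Background is
excluded because it would dominate the average.  Optimization is Adam at a
single fixed learning rate (default 1e-3), batch size 8.  After each epoch
the mean per-frame, per-class hard DICE on the validation set is recorded;
the checkpoint with the highest validation DICE is returned, ties to the
earliest epoch.  All randomness flows through seeded NumPy generators, so a
run is bit-reproducible on one machine.

**Grouped split.** Train/validation partitioning happens on subject ids, not
frames, so no infant contributes to both sides regardless of per-subject
frame counts; for phantoms (one study per subject) subject-level
disjointness is the strictest of the image/study/patient levels and implies
the others.

**Reference segmenter.** Geometry and decision tests must not depend on
training stochastics, so a deterministic intensity-and-morphology segmenter
is provided for phantom frames: smoothed-image thresholds (bright > 0.60 →
bone, dark < 0.18 → head candidate), small-object removal, a 3×3 closing on
bone, and largest-dark-component selection with a minimum area.  It is valid
for `speckle_strength ≤ 0.12` and `shadow_strength ≤ 0.5`; outside those
bounds the fixed thresholds begin to confuse shadow with the femoral head.
An undetected head yields an empty class (a landmark-absent result), not an
exception.

**Scaled-down training experiment.** The packaged experiment trains the
default network on 200 frames (50 subjects × 4 in-band frames) of native
128×128 low-noise phantoms for 20 epochs — sizes chosen so the whole
experiment is a desk-scale, single-core run — and reaches validation DICE
≈ 0.99, against an acceptance floor of 0.85.

## Geometry (`hipscreen.geometry`)

The two bone strokes usually touch at the rim and form a single connected
component, so the baseline/roof split cannot rely on connectivity.  The
decomposition runs a straight-line Hough transform (0.5° bins) over the
cleaned bone class, takes several peaks with an explicit low threshold (a
near-diagonal stroke can out-vote a shorter orthogonal one by more than
2×), seeds the baseline with the most vertical peak and the roof with the
strongest peak at least 15° away, then alternates nearest-line pixel
assignment (cap 5 px) with total-least-squares refinement.  TLS (PCA) is
used because boundary pixels err in both coordinates; the reported
`rms_residual_px` is the minor-axis standard deviation, which for a clean
3-px-wide stroke is ≈ 0.8 px, hence the 1.5 px default residual flag
threshold.

The femoral head is an algebraic (Kåsa) least-squares circle through the
boundary pixels of the largest head-class component; on exact rasterized
disks of radius ≥ 20 px it recovers center and radius within 1 px with rms
residual < 0.7 px.

*Alpha angle* is measured between the caudally oriented baseline ray and the
medially oriented roof ray at their intersection (the rim), so it is
invariant to sign flips of stored direction vectors and can exceed 90°;
angles below 1° raise a degenerate-configuration error.  *Coverage* uses the
Morin-style diameter fraction `clip((r + s)/2r, 0, 1)`; an independent
rasterized projection oracle (grid pitch 0.5 px) agrees within 0.01 for
radii ≥ 20 px.  `measure` never raises on incomplete masks: absent
landmarks, poor fits, small heads and degenerate angles become quality
flags and the corresponding index is left unset.

## Decision support (`hipscreen.decision`)

Frame adequacy requires both landmark classes with ≥ 50 px area, line fits
within the residual bound, circle fit within 2 px rms, and head radius
≥ 8 px; every violated criterion is reported as a reason code.  The capture
loop walks frames in acquisition order and stops at `min_adequate_frames`
(default 5 — small enough for desk-scale sweeps, large enough to exercise
aggregation).  Sweep-level indices are the **median** over adequate frames:
the median is order-free and robust to the occasional outlier measurement
that poor-quality frames produce.  Classification uses the conventional Graf
cutoffs, alpha ≥ 60° and coverage ≥ 50 %, with boundary equality counting
as healthy; both cutoffs are configuration values, not constants.  Whether a
production system would aggregate across frames or pick a single best frame
is an open design point; the median aggregate is this package's documented
choice.  End-to-end on phantoms, hips with ≥ 3° alpha margin and ≥ 0.05
coverage margin land on the correct side in 100 % of sweeps, the margins
comfortably absorbing the ≤ 2° measurement error.

## Screening statistics (`hipscreen.screenstats`)

The ledger is one CSV row per infant (latest status) with ISO-8601 dates and
a demographics column (`sex`) used for cohort composition.  `summarize`
counts four mutually exclusive initial-outcome categories (could-not-scan /
normal / suboptimal / follow-up) plus the follow-up sub-outcomes, and
recomputes every percentage from its integer count over unique infants with
half-away-from-zero rounding at a per-field precision spec — so a summary
can never disagree with its own counts.  The packaged 306-infant fixture is
generated deterministically by `build_pilot_cohort_ledger()` (the CSV and
the builder are asserted identical in tests); it reproduces the pilot
cohort's category counts, referral outcomes and sex ratio, with follow-ups
front-loaded in time to emulate the observed learning curve.  The fixture
stores counts only and every percentage is recomputed from them (e.g. the
26 follow-ups resolving normal report as 26/306 = 8.5 %), so no stored
rate can drift from its count.
Rolling follow-up rates are trailing-window proportions over records sorted
by (date, subject id), with could-not-scan infants included in the
denominator; infant-level roll-up of two hip decisions uses clinical
precedence FOLLOW_UP > SUBOPTIMAL (inconclusive scan) > NORMAL.

Referral confirmation with zero referrals is an undefined-rate error, not
0 — reporting 0 would read as "no referral confirmed".

## Numerical and degenerate-input choices

* DICE smoothing ε = 1 px (avoids 0/0 on empty classes; value is not
  critical and is exposed as a parameter).
* All-zero images cannot be mean-normalized and raise a degenerate-input
  error rather than returning NaNs.
* Validation-DICE ties select the earliest epoch; max-pool ties take the
  first element; ledger date ties break by subject id.
* Hough peak threshold is 15 % of the accumulator maximum (see geometry
  note above); line assignment cap 5 px; roof fits need ≥ 10 px support,
  circle fits ≥ 12 boundary px.
* Probabilities returned by `segment` are clipped to ≥ 1e-12 before
  renormalization after upsampling.

## Known limitations

* Phantom realism is schematic; no claim is made about performance on real
  ultrasound.  The production-scale network, its optimizer schedule and its
  training corpus are unknown here and deliberately out of scope.
* The reference segmenter's fixed thresholds are phantom-specific by design.
* Graf subtyping (IIa–IV), the beta angle and labrum localization are not
  computed; the decision surface is the 3-way call only.
* The alpha-angle range contract (0, 120] is wider than the phantom can
  generate (30–90°); values beyond 90° arise only from external masks.
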