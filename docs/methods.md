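# Methods

## Problem setting and data model

The package processes top-view thermal recordings: ordered sequences of 2-D
temperature rasters in °C with strictly increasing frame indices, a shared
frame geometry (default 240 × 320) and an optional per-frame camera
altitude. Temperatures are held as floats internally; on disk a sequence is
a multi-page 16-bit TIFF whose linear quantization (scale/offset sidecar) is
chosen per file to span the observed range, bounding the round-trip error by
half the quantization step. Pixel coordinates are (row, col), 0-based, row 0
at top, everywhere. Rescaling thermal frames to another resolution is not
performed; the pipeline operates at native thermal resolution.

## Detection

The per-frame threshold is the median frame temperature plus an offset
`c > 0` (default 5 °C). The median is used rather than the mean because the
hot objects themselves are outliers of the temperature distribution; for an
even pixel count the median is the mean of the two central order
statistics. Segmentation keeps pixels *strictly* above the threshold — the
strict inequality makes the all-background case (uniform frame) return an
empty mask unambiguously. Components are grouped 8-connected (animals are
compact; diagonal links should not split a body), whereas the 4-connected
cross is reserved for contour peeling below. Components smaller than
`min_area` (default 2 px) are discarded as single-pixel noise; the size
filter is configurable and deliberately permissive, since small objects must
survive to high altitude.

## Thermal signatures

For a blob mask the extraction is:

1. `i = −1`: dilate once with the 4-connected cross; the dilation minus the
   mask is the ring just outside the object. Its mean temperature anchors
   the signature to the immediate background.
2. `i = 0 … M`: record the mean over the 4-connected perimeter (mask minus
   its erosion, with out-of-frame counting as outside), remove the
   perimeter, repeat until the mask is empty.

Each peel strictly shrinks the mask, so the procedure terminates in at most
`area` iterations, and the interior contours partition the blob exactly.
Blobs touching the frame border get a clipped outer ring (flagged on the
signature); if the ring is empty (blob fills the frame) the `i = −1` sample
falls back to the `i = 0` value.

Normalization subtracts the `i = −1` outer-ring mean, making features
relative to the local background rather than absolute temperature — the
property that lets the classifier survive sun-heated scenes. The phrase
"first contour" is ambiguous between the outer ring and the first interior
perimeter; this package uses the outer ring by default because
background-relative contrast is the physically meaningful quantity, and
exposes `baseline="interior"` for the other reading. The `i = −1` sample
(exactly 0 after normalization) is kept in the transform input: it carries
the edge-step geometry that separates animals from gradual mounds.

## DCT parameterization

Signature length varies with object size, so signatures are embedded in a
fixed 7-dimensional space by a discrete cosine transform. The convention is
the orthonormal type-II DCT additionally divided by √N. Under it a constant
signal of value *v* maps to coefficients (v, 0, 0, …) for **any** length —
without the √N compensation the "length-invariance" motivation for the DCT
fails. Coefficients beyond the signature length are zero-padded.
Reconstruction multiplies back by √(length) and inverts; with no truncation
the round trip is exact, and truncation error obeys Parseval's identity
under the orthonormal convention. `energy_fraction` reports retained
squared-coefficient mass over total (defined as 1 for an all-zero
signature). Seven coefficients were adopted as the default because they
retain ≥ 95 % of signature energy for ≥ 95 % of synthetic animal signatures,
measured by the acceptance script.

## kNN classification

Euclidean distance on the raw coefficients, `k = 11`, majority vote;
`g_A = k_A / k` is exposed as the animal likelihood. No feature scaling is
applied by default — the coefficients share °C-derived units — but z-scoring
is available (`standardize=True`). Distance ties at the k-th rank are broken
by training-set insertion order (stable sort), making results reproducible
across runs and platforms; away from ties the classifier agrees with
scikit-learn's `KNeighborsClassifier`, which serves as an independent
cross-check in the tests. With `k` odd and two classes no vote tie is
possible, so the label is exactly `g_A > 0.5`. The default training-set
composition is 140 animal and 359 non-animal vectors: the non-animal class
is more heterogeneous and needs more data.

## Tracking and belief

Each active track predicts a guess region whose center extrapolates the last
inter-frame movement (a one-member track predicts in place) and whose radius
is a fixed 190 px gate — the maximum positional uncertainty tolerated
between consecutive frames; it does not grow with missed frames.
Per frame, candidate (track, detection) pairs within the gate are committed
greedily by increasing distance, one detection per track. Greedy assignment
(rather than globally optimal matching) was chosen for simplicity and
determinism; in the sparse scenes the tracker targets, gate conflicts are
rare and greedy coincides with the optimal pairing (the tests verify this on
2 × 2 cases in that regime). Unmatched detections open new tracks; a track
that accepts nothing increments a missed counter and terminates once the
counter exceeds 3. Missed frames do not change the belief — no observation,
no update.

The belief starts at the indifferent prior 0.5 and absorbs each accepted
detection's clamped likelihood `g ∈ [0.05, 0.95]` via Bayes' rule; in
log-odds the update is additive, so after the first observation the belief
equals the clamped likelihood, the final belief is order-invariant, constant
evidence converges geometrically toward 0 or 1, and the clamp keeps the
belief strictly inside (0, 1) so contrary evidence can always recover it. A
track is identified at end of recording (online mid-track identification is
possible via the running belief but is not the default): animal iff the last
belief strictly exceeds 0.5 (exactly 0.5 → non-animal), and all member
detections inherit the final label. Tracks with ≤ 5 members are flagged
unidentified for evaluation.

## Metrics

Balanced accuracy = (sensitivity + specificity)/2 with animal as positive
class; it is invariant to class prevalence, which matters because animal
detections thin out with altitude. Altitude-banded evaluation uses half-open
intervals `[low, high)` (defaults 3–10 m and 10–20 m), so a record at
exactly 10 m belongs to the far band only. Reports round to 4 decimals
internally and print 3. The pixel-footprint model is
`round(pixels_ref · (alt_ref/alt)²)`, referenced to 305 px at 5 m for a
0.05 m² animal.

## Synthetic scenes

The generator emulates the study conditions: backgrounds drawn from
15–23 °C with independent per-pixel Gaussian noise (sd 0.2–0.4 °C in the
randomized samplers, 0.3 default); sparse objects placed without overlap
(overlap raises); and three object classes whose radial profiles, additive
over background, reproduce the distinguishing signature shapes:

* **animal** — footprint 200–420 px at the 5 m reference (around the
  305 px / 0.05 m² reference), core offset 8–15 °C, rising across a
  1–3 px boundary shell onto a plateau tilted 10 % toward the center. The
  steep shell models heat escaping past the insulating coat at the body
  outline; the tilt keeps interior contour means strictly increasing.
* **lamp** — 60–160 px uniform disk at +25–60 °C (halogen spotlights:
  small, very hot, flat signature).
* **molehill** — 300–700 px linear cone at +5.5–8 °C (wide, shallow,
  gently graded sun-warmed soil).

Footprints scale with (reference altitude / altitude)²; pixel coverage is
anti-aliased over a half-pixel band so sub-pixel objects mix with the
background instead of vanishing abruptly. Optionally, `contrast_decay`
multiplies every core offset by `exp(−decay · (altitude − reference))`,
emulating the loss of apparent contrast with sensor distance. It is **off
by default**; altitude-sweep experiments (tests and the acceptance script)
use decay = 0.04 /m — at that rate an animal's apparent offset falls to
about 60 % at 18 m, which is the regime where single-frame classification
becomes genuinely ambiguous and temporal aggregation pays off. Without the
decay, geometric footprint loss alone leaves the three synthetic classes
separable at any altitude at which they are detectable, so per-frame
classification saturates.

`generate_training_set` renders randomized single-object scenes per class
(non-animal scenes alternate lamps and molehills), resampling undetected
renders up to a bounded retry count, and returns exact class counts
(defaults 140/359). `generate_evaluation_set` instead keeps only detected
renders, so at far-range altitudes faint classes thin out as in real
sweeps. All outputs are pure functions of spec + seed.

What the generator does **not** emulate: radiative physics (emissivity,
atmospheric attenuation beyond the single exponential contrast term),
camera motion and blur, posture variation, vegetation occlusion, correlated
sensor noise, and the real fur/feather signature shapes beyond their
qualitative steep-edge character. Passing synthetic checks therefore
demonstrates internal consistency of the pipeline and the direction of its
qualitative behaviors (altitude degradation, tracking gain), not field
performance.

## Problem sizes and numerical choices

The test suite and acceptance script use deliberately compact conditions
chosen as representative: training sets of 60/100 vectors for shared
fixtures and the full 140/359 for the leave-one-out measurement; 6–8
descending sweeps of 30 frames (18 m → 4 m) for the tracking-gain
measurement; 12 animals per altitude at 8 altitudes (5–40 m) for the
detection curve; 100 signatures for the DCT energy share. Seeds are fixed
in tests and derived from `--seed` in the acceptance script. Degenerate
inputs are defined explicitly: empty masks raise; an all-zero signature has
energy fraction 1; confusion matrices with an empty class margin raise
naming the margin; detection performance requires at least one true object.
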