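# Methods

## The measurement problem

A plantar foot ulcer is photographed repeatedly over weeks by a patient
or carer with a phone camera, flash on, foot filling most of the frame
against a dark background. No fiducial object is in the scene, so
absolute wound area is unrecoverable; the quantity tracked is the
ulcer-to-foot pixel ratio, normalised to the first ("baseline") check:

    relative_t = 100 * (ulcer_px / foot_px)_t / (ulcer_px / foot_px)_0

Two assumptions underpin this: (1) the foot's projected area is stable
across checks (same foot, roughly plantar view), and (2) both areas are
measured in the same image, so any common scale factor — camera
distance, resolution, crop — cancels. Per-check normalisation by the
foot area of *that* image is used (rather than freezing the baseline
photo's foot area as a fixed scale), which is what makes the metric
robust to distance changes between checks.

## Segmentation

Marker-controlled watershed on the morphological gradient, in two
stages:

1. luminance `L = round(0.299 R + 0.587 G + 0.114 B)` (half-up);
2. gradient `g = dilation(L) − erosion(L)` with a 3×3 cross
   structuring element, borders replicated;
3. priority flood from the rasterised scribble markers: background +
   foot strokes for stage one over the whole image, foot + ulcer
   strokes for stage two restricted to the stage-one foot mask.

### Flood semantics (normative)

Pixels are popped in ascending gradient order; ties are broken
first-in-first-out by queue-insertion order (initial marker pixels are
visited in raster order). A popped pixel takes the label of the single
positive label among its 4-neighbours (which is the front that queued
it in the ordinary case); if its 4-neighbours already carry two
different positive labels it becomes a watershed-line pixel (value 0).
Line pixels still enqueue their unvisited neighbours, carrying the
label of the front that reached the line first — without this, a pixel
whose only path from any marker runs through a meeting point of two
fronts would never be visited. Flooding uses 4-connectivity; outlines
use 8-connectivity (Moore boundary tracing). These choices are fixed:
the test suite contains an independent brute-force implementation of
the same rules (linear-scan minimum selection instead of a heap) and
requires pixel-for-pixel agreement on random instances.

With corner-seeded floods on a flat gradient, meeting fronts *can*
produce watershed-line pixels wherever a popped pixel already sees both
labels; the partition property asserted is therefore "every in-region
pixel is labelled or on the line", not "no line pixels on flat images".

### Post-processing

- Foot mask: largest 4-connected foot-labelled component, interior
  holes filled (the ulcer is darker than skin but is part of the foot
  for scaling purposes).
- Ulcer mask: union of ulcer-labelled components containing an ulcer
  marker. A candidate whose mean luminance is within
  `min_edge_contrast` (default 15 grey levels) of the skin ring around
  it is discarded: a marker tapped onto featureless skin would
  otherwise claim an arbitrary flood cell bounded by nothing. Genuine
  ulcers in the synthetic scenes have ≥ 40 levels of contrast, so the
  guard only fires on spurious seeds.
- Watershed-line pixels are excluded from all area counts. Because the
  generator renders a one-pixel soft transition just *outside* each
  region boundary (see below), the line settles on transition pixels
  that belong to neither region's ground truth, and the bias this
  exclusion introduces is well under 1% of area for feet larger than
  ~100 px across.
- Quality flags: foot touching the image border, foot area outside
  5–80% of the frame, ulcer outline 8-adjacent to the foot outline, and
  empty ulcer mask. Flags are surfaced, never silently "corrected" —
  the user is asked to retake the photo instead.

## Synthetic scenes

The generator emulates the photographic contract, not anatomy: a bright
skin-coloured silhouette (vertical ellipse, semi-axis ratio 0.42, five
toe lobes along the upper arc) on a dark background, a darker red
ulcer disc inside it, radial multiplicative flash falloff
`1/(1 + k·(r/r_max)²)`, and i.i.d. Gaussian intensity noise clipped to
[0, 255]. The pipeline never assumes anatomy, so any smooth
bright-on-dark shape exercises it; realism is deliberately traded for
exact ground truth.

Defaults: 256×256 px, foot spanning 70% of the image height (≈ 17% of
the frame area), ulcer fraction 0.05, falloff 0.3, noise σ = 2, ulcer
luminance contrast 100. Resolution and distance of real phone photos
are unstandardised, so the defaults are mid-range choices exposed as
parameters rather than claims about real data.

Rendering details that matter:

- The ulcer radius is bisected until the realised pixel fraction is
  within ±0.005 of the target; infeasible targets raise.
  `realized_ulcer_fraction` is the exact pixel ratio of the stored
  masks.
- Region boundaries carry a one-pixel transition ring just outside the
  mask, mixed 25% inner / 75% outer colour, emulating optical blur.
  This gives the morphological gradient an asymmetric profile (low step
  on the outer side, high step on the region's true edge pixels, full
  step on the ring), which makes the flood claim each region's true
  pixels deterministically and park the watershed line on the ring.
  Without it, a hard step edge produces a two-pixel flat gradient band
  and the line lands raggedly on either side, costing a few percent of
  area at typical ulcer sizes.
- Distractors reproduce documented failure modes: `leg_skin` draws
  skin-coloured leg/arm regions connected to the foot at the top of the
  frame, `bright_spot` a high-intensity disc in the background. A good
  background loop drawn between foot and leg seeds background markers
  across the connection, which is what actually excludes the leg.
- Scribble generation mirrors the instructed protocol: a closed loop
  hugging the foot at ≥ 3 px clearance (traced on the Euclidean
  distance field), two strokes on clean skin, and a short dash or tap
  at the ulcer's interior point of maximum boundary distance.
  `edge_crossing` drags the ulcer stroke across the wound edge;
  `missing_background` omits the loop. Stroke rasterisation is
  Bresenham polylines dilated by a disc (default radius 2 px,
  approximating a stylus tip); later strokes overwrite earlier ones,
  matching a redraw-to-correct interaction.

What the generator does **not** model: non-plantar views, oblique
camera angles, multiple wounds, specular highlights on moist tissue,
depth/curvature foreshortening, JPEG artefacts. Tests passing on these
scenes show the algorithmic chain is correct and scale-stable; they do
not certify accuracy on real clinical photographs.

## Series logic

- The first appended check fixes the baseline fraction and reads
  exactly 100%; a baseline with no visible ulcer is rejected (the
  workflow assumes the first check is taken in clinic on an existing
  wound).
- Goal: reached iff any non-outlier check within `horizon_days`
  (default 28) of baseline has relative size ≤ 100 − `reduction_pct`
  (default 50). The boundary is inclusive: attaining exactly 50% counts.
- Outliers: relative size > 300% (absolute cap) or > 5× the series
  median. Both branches are configurable; the baseline is never
  flagged. The display layer can exclude or keep flagged points
  (`graph_points(exclude_outliers=...)`), since either behaviour is
  defensible for a progress graph.
- Feedback tiers: an untrusted latest check (outlier or geometric
  flags) always yields *check_photo*; otherwise *goal_reached* (the
  only verbatim-fixed message: “You’ve Reached Your Goal!”), else the
  trend between the last two trusted checks with a ±5-percentage-point
  steady band. The band and tier table are this package's design; only
  the goal threshold and message are externally fixed.

## Engagement classification

From foot-check events only (generic app interactions are logged but
not counted): ≥ 20 checks over the study → continuous, < 10 → failed,
otherwise temporary. The published bounds leave a count of exactly 19
unassigned ("≥10 and <19" vs "≥20"); it is assigned to temporary so the
classifier is total, which leaves both sweep-recovered thresholds
(smallest continuous = 20, smallest non-failed = 10) unchanged. The
weekly rate is `count / (study_days / 7)`, default study length 84
days.

The archetype generator samples: continuous 20–45 checks uniformly over
the study; temporary 10–19 with a ≥ 3-week gap in the middle; failed
1–9 all within the first three weeks. Counts are sampled inside the
class bounds, so generator → classifier round-trips by construction;
the tests verify the date patterns (gap length, early stop)
independently.

## Problem sizes and numerics

The test suite and acceptance script run synthetic scenes at 256×256
(the generator default) — large enough that boundary-pixel effects are
below the asserted tolerances, small enough that a full two-stage
segmentation takes ~0.3 s. Area-recovery statistics use 20 seeds with
target fractions drawn in [0.02, 0.15]; scale-invariance compares 1×
against 2× nearest-neighbour upscaling on a noiseless scene; the
trajectory check runs five weekly checks of an exponential healing
curve (rate 0.8/week) through the full image pipeline. All randomness
flows through `numpy.random.default_rng` seeded per call; identical
parameters give byte-identical scenes.

## Known limitations

- Behavioural equivalence with any particular historical app build is
  not claimable; the flood semantics above are this package's
  specification, checked against its own oracle.
- The contrast guard assumes wounds darker than surrounding skin;
  hypergranulation or callus brighter than skin would need a sign-aware
  variant.
- Relative scaling silently absorbs true foot-area changes (oedema,
  partial amputation) into the wound metric.
- Single wound per foot; the smaller of two wounds would be merged or
  missed depending on scribbles.
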