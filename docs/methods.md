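# Methods

## The spray model and its assumptions

The simulated sprayer travels along the image width; its boom, carrying *n*
independently switched nozzles, lies along the image height. Each nozzle can
only wet its own horizontal strip, so actuating a nozzle for a detection wets a
strip-tall rectangle. The model makes deliberately strong simplifications:

- **Whole-containment hit criterion.** A weed counts as sprayed only when its
  ground-truth box is entirely inside the wetted union — a 99%-covered weed
  counts as missed. This is the conservative reading of "hit" and is
  implemented literally with exact pixel-set arithmetic (no epsilon anywhere).
- **Spray confined to the image.** Proposed rectangles are clipped at the image
  border; there is no carry-over into neighbouring frames. Consequently a weed
  touching the border can still be sprayed (clipping never removes any pixel of
  detection ∩ strip), but the model cannot represent spray landing outside the
  camera's view.
- **No nozzle physics.** Spray drift, actuation latency, pressure-dependent fan
  shape and inter-frame timing are out of scope; the nozzle is an ideal
  rectangle switch.

### Geometry conventions

Boxes are integer-pixel, half-open `[x_min, x_max) × [y_min, y_max)`, origin
top-left. Every area is an exact pixel count, which makes the sweep-line union
bit-identical to a boolean mask rasterization — the property the test suite
checks on hundreds of random scenes.

When *H* is not divisible by *n*, strip boundaries fall at `floor(k·H/n)`
(heights differ by at most one pixel) while the nominal nozzle width used in
the spray-width rule `max(ceil(H/n), w)` is the ceiling — a nozzle is never
modelled narrower than its physical footprint, so uneven division can
slightly over-spray but never under-spray.

The paper-level rule fixes a spray rectangle's height and width but not its
horizontal placement; we centre it on the detection's x-range, splitting any
excess width floor-left / ceil-right, then clip to the image. Centring is the
natural reading of a nozzle aimed at a target and keeps the proposal
deterministic; the containment guarantee (each rectangle ⊇ detection ∩ strip)
holds regardless of the split convention.

Only weed-class detections at or above the confidence threshold (default 0.05,
a typical test-time operating point for the detectors this model evaluates)
trigger spraying; crop detections and crop ground truth never influence either
metric. A dataset with zero ground-truth weeds raises an explicit
undefined-metric error rather than silently reporting 0.

### Consequences worth knowing

- With detections identical to ground truth, WCR is exactly 100 for every
  feasible *n*: each strip-intersecting part of a weed box is covered by its
  own proposal.
- For dyadic refinements (2*n* nozzles, *H* divisible by 2*n*), the finer spray
  region is a pixel subset of the coarser one, so area sprayed is monotone
  non-increasing and WCR non-increasing along n = 1, 2, 4. For non-nested
  configurations (e.g. n = 3) no such guarantee exists.
- Area sprayed can exceed what the detections' own area suggests by a large
  factor at small *n* — one broad nozzle wets a full-height band per detection.

## Detection metrics

AP is the literal non-interpolated sum Σ(Rₖ−Rₖ₋₁)·Pₖ over the pooled,
confidence-ranked detection list (ties broken by input order); a COCO-style
101-point interpolated variant is available but off by default. Matching is
greedy per image and class: highest-confidence detection first, each matched to
the unmatched ground truth of highest IoU above the threshold. mAP averages
over the COCO grid 0.50:0.05:0.95 (10 thresholds, configurable) and then over
the classes that have ground truth; explicitly requesting a class without any
ground-truth boxes raises the undefined-metric error rather than contributing
a silent zero.

## Synthetic scenes

The generator emulates the summary statistics of an annotated sugar-beet field
dataset: Poisson-distributed counts per image (defaults 5.190 weeds, 3.725
beets), box areas log-normal with mean area fraction 0.002 (weeds) and 0.033
(beets) of the image and log-spread σ = 0.5, log-normal aspect ratios around 1
(σ = 0.3), uniform placement, default canvas 640 × 360 (a 1920 × 1080 frame
resized to a 640 long side; 360 is divisible by 1–4 nozzles, keeping the
nesting property exactly testable). Only the count and size means are
calibrated to published dataset statistics; Poisson counts and log-normal
sizes/aspects are this package's modelling choices, and all parameters are
exposed.

What the generator does **not** model: spatial structure (crop rows,
clustering), occlusion statistics, plant growth stages, or image content of
any kind — scenes are boxes, not pixels. Tests passing on synthetic scenes
therefore validate the *metric computations and their invariants*, not any
claim about how a particular detector performs on real fields.

The corruption model emulates detector error modes: independent per-box misses
(`fn_rate`), Poisson spurious weed detections per image (`fp_rate`), Gaussian
jitter on each box edge independently (re-sorted and clipped to stay valid),
and uniform confidence draws — TP-like boxes in [0.5, 1.0], FP-like in
[0.05, 0.6]. The noisy-sweep study conditions used in tests and in the
acceptance script are fn_rate = 0.1, fp_rate = 1.0, jitter σ = 2 px over 500
scenes: a mid-quality detector on which the coverage/area trade-off across
nozzle counts is clearly visible.

## Capacity planner

Cameras along the boom use a ceiling division (full coverage, no gaps):
`ceil(24000/380) = 64` for the default geometry with the short footprint edge
along the boom, `ceil(24000/670) = 36` with the long edge along the boom. The
per-camera frame rate is speed over the along-travel footprint edge (no
overlap between consecutive frames), and the aggregate rate is the product.
Unit conversions use the exact statutory factors (1 mph = 0.44704 m/s =
1.609344 km/h), with rounding only at display time.

## Numerical and design notes

- The rectangle union is a coordinate-compression sweep; results are invariant
  to input order and agree exactly with rasterization (asserted, not assumed).
- Containment is tested as `area(region ∩ box) == area(box)` in integers.
- COCO bbox floats are rounded half-away-from-zero onto the pixel grid and
  clipped to the image; boxes that become empty are dropped with a logged
  warning so record counts stay auditable. YOLO round trips are exact to six
  decimals of the normalised coordinates.
- Percentages carry full float precision internally; 1-decimal rounding
  happens only in CLI display.
- Problem sizes in the test suite and acceptance script (200–500 scenes,
  10,000 for generator calibration) were chosen to make sampling checks
  decisive (3-standard-error bands) while keeping a full run in seconds.

## Known limitations

- Non-contiguous frames: spray cannot extend across image boundaries.
- The hit criterion is binary whole-containment; no partial-coverage credit.
- The generator's independence assumptions (no occlusion, no spatial
  structure) make synthetic WCR/area values illustrative, not predictive of
  any real dataset.
- The capacity planner treats the camera footprint as an empirical constant;
  optics are not modelled.
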