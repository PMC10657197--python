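"""Strip-based spray model: nozzle strips, spray-area proposal, WCR and area sprayed.

The model simulates a boom sprayer driving across the image width with n
independently switched nozzles stacked along the image height.  The image
is split into n horizontal strips, one per nozzle.  Every weed detection
that vertically overlaps a strip proposes a spray rectangle in that strip:
strip-tall, and as wide as the detection or the nominal nozzle footprint
``H/n``, whichever is larger.  The union of the proposed rectangles is the
region the sprayer would wet; a ground-truth weed counts as hit only when
it is wholly contained in that union.

Two dataset-level figures summarise a run:

* weed coverage rate (WCR) — the percentage of ground-truth weed boxes
  wholly contained in the spray region, pooled over all images;
* area sprayed — the percentage of total image pixels covered by the
  spray region, a proxy for herbicide volume (the saving is its
  complement to 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import AlignmentError, ConfigurationError, UndefinedMetricError, ValidationError
from .geometry import PixelBox, SprayRegion, union_region
from .records import Detection, ImageRecord, WEED

#: Test-time confidence threshold used throughout unless overridden.
DEFAULT_CONFIDENCE_THRESHOLD = 0.05

__all__ = [
    "DEFAULT_CONFIDENCE_THRESHOLD",
    "NozzleConfig",
    "Strip",
    "SprayResult",
    "DatasetSprayMetrics",
    "strip_decomposition",
    "propose_spray_areas",
    "spray_union",
    "is_sprayed",
    "evaluate_image",
    "weed_coverage_rate",
    "area_sprayed",
    "herbicide_saving",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class NozzleConfig:
    """Number of nozzles n stacked along the image height."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"nozzle count must be >= 1, got {self.n}")

    def nominal_nozzle_width(self, height: int) -> int:
        """Nominal per-nozzle footprint in pixels, ``ceil(H / n)``.

        The ceiling means an uneven division never under-sprays.
        """
        return -(-height // self.n)


@dataclass(frozen=True)
class Strip:
    """Horizontal band of the image addressed by one nozzle (full x-range)."""

    index: int
    y_min: int
    y_max: int

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def overlaps(self, box: PixelBox) -> bool:
        return box.y_min < self.y_max and self.y_min < box.y_max


@dataclass(frozen=True)
class SprayResult:
    """Per-image spray simulation output."""

    image_id: object
    spray_boxes: tuple[PixelBox, ...]
    region: SprayRegion
    sprayed_flags: tuple[bool, ...]
    num_gt_weeds: int
    image_area: int


@dataclass(frozen=True)
class DatasetSprayMetrics:
    """Pooled dataset metrics, all on the 0–100 percent scale."""

    wcr: float
    area_sprayed: float
    herbicide_saving: float
    per_image: tuple[SprayResult, ...]


def strip_decomposition(height: int, n: int) -> list[Strip]:
    """Split ``[0, height)`` into n strips with boundaries at ``floor(k*height/n)``.

    The strips are disjoint, ordered and exactly cover the image height;
    their heights differ by at most one pixel.
    """
    if n < 1 or n > height:
        raise ConfigurationError(
            f"nozzle count must satisfy 1 <= n <= image height, got n={n}, height={height}"
        )
    bounds = [(k * height) // n for k in range(n + 1)]
    return [Strip(index=k, y_min=bounds[k], y_max=bounds[k + 1]) for k in range(n)]


def propose_spray_areas(
    detections: Sequence[Detection],
    image: ImageRecord,
    cfg: NozzleConfig,
) -> list[PixelBox]:
    """Propose one spray rectangle per (weed detection, intersecting strip) pair.

    Each rectangle spans its strip's full vertical extent and is
    ``max(ceil(H/n), w)`` wide, centred on the detection's x-range
    (excess width split floor-left / ceil-right) and clipped to the
    image.  Clipping cannot break containment because detections lie
    inside the image, so every proposed box contains detection ∩ strip.

    ``detections`` are expected to be pre-filtered to the weed class and
    the desired confidence threshold (see :func:`evaluate_image`).
    """
    strips = strip_decomposition(image.height, cfg.n)
    nominal = cfg.nominal_nozzle_width(image.height)
    boxes: list[PixelBox] = []
    for det in detections:
        if det.class_label != WEED:
            continue
        spray_width = max(nominal, det.box.width)
        pad = spray_width - det.box.width
        x0 = det.box.x_min - pad // 2
        x1 = det.box.x_max + (pad - pad // 2)
        for strip in strips:
            if not strip.overlaps(det.box):
                continue
            clipped = PixelBox(x0, strip.y_min, x1, strip.y_max).clip(image.width, image.height)
            assert clipped is not None  # detection lies inside the image
            boxes.append(clipped)
    return boxes


def spray_union(boxes: Sequence[PixelBox]) -> SprayRegion:
    """Exact union of the proposed spray rectangles (order-independent)."""
    return union_region(boxes)


def is_sprayed(gt_box: PixelBox, region: SprayRegion) -> bool:
    """Whole-containment test: every pixel of ``gt_box`` lies in the union.

    A weed partially covered by spray — even 99% — does not count; the
    containment is exact pixel-set containment with integer arithmetic.
    """
    return region.contains(gt_box)


def evaluate_image(
    image: ImageRecord,
    cfg: NozzleConfig,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> SprayResult:
    """Run the spray simulation for one image.

    Detections are filtered to weed class at or above the confidence
    threshold; crop-class ground truth never enters the sprayed flags.
    """
    if cfg.n > image.height:
        raise ConfigurationError(
            f"image {image.image_id!r}: n={cfg.n} exceeds image height {image.height}"
        )
    kept = image.weed_detections(confidence_threshold)
    boxes = propose_spray_areas(kept, image, cfg)
    region = spray_union(boxes)
    weeds = image.gt_weeds()
    flags = tuple(is_sprayed(a.box, region) for a in weeds)
    return SprayResult(
        image_id=image.image_id,
        spray_boxes=tuple(boxes),
        region=region,
        sprayed_flags=flags,
        num_gt_weeds=len(weeds),
        image_area=image.area,
    )


def weed_coverage_rate(results: Sequence[SprayResult]) -> float:
    """Pooled WCR: 100 × (weeds wholly sprayed) / (total ground-truth weeds)."""
    total = sum(r.num_gt_weeds for r in results)
    if total == 0:
        raise UndefinedMetricError(
            "weed coverage rate is undefined: no ground-truth weeds in the dataset"
        )
    hit = sum(sum(r.sprayed_flags) for r in results)
    return 100.0 * hit / total


def area_sprayed(results: Sequence[SprayResult], images: Sequence[ImageRecord]) -> float:
    """Pooled area sprayed: 100 × Σ|S_i| / Σ(W_i · H_i)."""
    ids_r = sorted(map(repr, (r.image_id for r in results)))
    ids_i = sorted(map(repr, (im.image_id for im in images)))
    if ids_r != ids_i:
        raise AlignmentError("results and images cover different image sets")
    if not images:
        raise UndefinedMetricError("area sprayed is undefined on an empty dataset")
    return 100.0 * sum(r.region.area for r in results) / sum(im.area for im in images)


def herbicide_saving(area_sprayed_pct: float) -> float:
    """Herbicide saving relative to broadcast spraying: 100 − area sprayed."""
    if not (0.0 <= area_sprayed_pct <= 100.0) or math.isnan(area_sprayed_pct):
        raise ValidationError(f"area sprayed must be in [0, 100], got {area_sprayed_pct}")
    return 100.0 - area_sprayed_pct


def evaluate_dataset(
    images: Sequence[ImageRecord],
    cfg: NozzleConfig,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> DatasetSprayMetrics:
    """Spray-simulate every image and pool WCR / area sprayed / saving."""
    results = tuple(evaluate_image(im, cfg, confidence_threshold) for im in images)
    sprayed = area_sprayed(results, images)
    return DatasetSprayMetrics(
        wcr=weed_coverage_rate(results),
        area_sprayed=sprayed,
        herbicide_saving=herbicide_saving(sprayed),
        per_image=results,
    )
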