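"""Synthetic field-scene generator and detection-corruption model.

Generates images statistically resembling an annotated sugar-beet field
dataset: Poisson counts of weed and crop bounding boxes per image,
log-normal box sizes expressed as fractions of the image area, uniform
placement.  Defaults target the Lincoln-beet dataset statistics: 5.190
weeds and 3.725 beets per image on average, with weed boxes occupying on
average 0.2% of the image and beet boxes 3.3%.

A separate corruption model turns ground truth into detector-like output
with configurable false-negative drops, Poisson false positives, Gaussian
edge jitter and confidence scores — enough structure to exercise every
spray and detection metric without any real dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .geometry import PixelBox, rasterize_union_area
from .records import Annotation, Detection, ImageRecord, CROP, WEED
from .spray import NozzleConfig, propose_spray_areas

__all__ = [
    "SceneGenParams",
    "CorruptionParams",
    "generate_scene",
    "generate_dataset",
    "corrupt_detections",
    "corrupt_dataset",
    "Fixture",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class SceneGenParams:
    """Scene statistics; defaults emulate the Lincoln-beet dataset.

    Box areas are log-normal with the given mean area fraction and a
    log-scale spread ``size_sigma``; aspect ratios (width/height) are
    log-normal around 1.  Boxes may overlap freely (occlusion structure
    is not modelled).
    """

    width: int = 640
    height: int = 360
    mean_weeds: float = 5.190
    mean_crops: float = 3.725
    weed_area_fraction: float = 0.002
    crop_area_fraction: float = 0.033
    size_sigma: float = 0.5
    aspect_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("image dimensions must be positive")
        if self.mean_weeds < 0 or self.mean_crops < 0:
            raise ValidationError("mean counts must be >= 0")
        for f in (self.weed_area_fraction, self.crop_area_fraction):
            if not (0.0 < f < 1.0):
                raise ValidationError(f"area fraction must be in (0, 1), got {f}")


@dataclass(frozen=True)
class CorruptionParams:
    """Detector-noise model applied to ground truth.

    Each GT box is dropped with probability ``fn_rate``; survivors get
    independent Gaussian jitter (std ``jitter_sigma`` pixels) on every
    edge and a confidence drawn uniformly from ``tp_confidence``.
    ``Poisson(fp_rate)`` spurious weed boxes are added per image with
    sizes like real weeds and confidences from ``fp_confidence``.
    """

    fn_rate: float = 0.0
    fp_rate: float = 0.0
    jitter_sigma: float = 0.0
    tp_confidence: tuple[float, float] = (0.5, 1.0)
    fp_confidence: tuple[float, float] = (0.05, 0.6)
    fp_area_fraction: float = 0.002
    fp_size_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.fn_rate <= 1.0):
            raise ValidationError(f"fn_rate must be in [0, 1], got {self.fn_rate}")
        if self.fp_rate < 0 or self.jitter_sigma < 0:
            raise ValidationError("fp_rate and jitter_sigma must be >= 0")


def _sample_box(
    rng: np.random.Generator,
    width: int,
    height: int,
    area_fraction: float,
    size_sigma: float,
    aspect_sigma: float,
) -> PixelBox:
    # log-normal with mean equal to the target fraction
    mu = math.log(area_fraction) - size_sigma**2 / 2
    frac = float(rng.lognormal(mu, size_sigma))
    area = max(frac, 1.0 / (width * height)) * width * height
    ratio = float(rng.lognormal(0.0, aspect_sigma))
    w = max(1, min(width, round(math.sqrt(area * ratio))))
    h = max(1, min(height, round(math.sqrt(area / ratio))))
    x0 = int(rng.integers(0, width - w + 1))
    y0 = int(rng.integers(0, height - h + 1))
    return PixelBox(x0, y0, x0 + w, y0 + h)


def generate_scene(
    params: SceneGenParams,
    seed: int | np.random.Generator,
    image_id: object = 0,
) -> ImageRecord:
    """Draw one scene; fully reproducible from the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_weeds = int(rng.poisson(params.mean_weeds)) if params.mean_weeds > 0 else 0
    n_crops = int(rng.poisson(params.mean_crops)) if params.mean_crops > 0 else 0
    anns = []
    for i in range(n_weeds):
        box = _sample_box(rng, params.width, params.height,
                          params.weed_area_fraction, params.size_sigma, params.aspect_sigma)
        anns.append(Annotation(box=box, class_label=WEED, id=f"{image_id}-w{i}"))
    for i in range(n_crops):
        box = _sample_box(rng, params.width, params.height,
                          params.crop_area_fraction, params.size_sigma, params.aspect_sigma)
        anns.append(Annotation(box=box, class_label=CROP, id=f"{image_id}-c{i}"))
    return ImageRecord(
        image_id=image_id,
        width=params.width,
        height=params.height,
        annotations=tuple(anns),
        metadata={"synthetic": True},
    )


def generate_dataset(
    params: SceneGenParams, n_images: int, seed: int
) -> list[ImageRecord]:
    """Draw ``n_images`` independent scenes from one seeded stream."""
    rng = np.random.default_rng(seed)
    return [generate_scene(params, rng, image_id=i) for i in range(n_images)]


def _jitter_box(
    rng: np.random.Generator, box: PixelBox, sigma: float, width: int, height: int
) -> PixelBox:
    if sigma == 0.0:
        return box
    edges = np.asarray(box.as_tuple(), dtype=float) + rng.normal(0.0, sigma, size=4)
    x0, x1 = sorted((edges[0], edges[2]))
    y0, y1 = sorted((edges[1], edges[3]))
    x0 = int(np.clip(round(x0), 0, width - 1))
    y0 = int(np.clip(round(y0), 0, height - 1))
    x1 = int(np.clip(round(x1), x0 + 1, width))
    y1 = int(np.clip(round(y1), y0 + 1, height))
    return PixelBox(x0, y0, x1, y1)


def corrupt_detections(
    scene: ImageRecord,
    params: CorruptionParams,
    seed: int | np.random.Generator,
) -> ImageRecord:
    """Derive detector-like detections from a scene's ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dets: list[Detection] = []
    lo, hi = params.tp_confidence
    for ann in scene.annotations:
        if params.fn_rate > 0 and rng.random() < params.fn_rate:
            continue
        box = _jitter_box(rng, ann.box, params.jitter_sigma, scene.width, scene.height)
        conf = float(rng.uniform(lo, hi))
        dets.append(Detection(box=box, class_label=ann.class_label, confidence=conf))
    n_fp = int(rng.poisson(params.fp_rate)) if params.fp_rate > 0 else 0
    flo, fhi = params.fp_confidence
    for _ in range(n_fp):
        box = _sample_box(rng, scene.width, scene.height,
                          params.fp_area_fraction, params.fp_size_sigma, 0.3)
        dets.append(Detection(box=box, class_label=WEED,
                              confidence=float(rng.uniform(flo, fhi))))
    return scene.with_detections(dets)


def corrupt_dataset(
    scenes: Sequence[ImageRecord], params: CorruptionParams, seed: int
) -> list[ImageRecord]:
    rng = np.random.default_rng(seed)
    return [corrupt_detections(s, params, rng) for s in scenes]


@dataclass(frozen=True)
class Fixture:
    """A tiny hand-checkable scene with frozen expected metric values.

    ``expected`` maps nozzle count n to ``{"wcr": ..., "area_sprayed": ...}``
    computed with the pixel-rasterization oracle at fixture-creation time.
    """

    name: str
    scene: ImageRecord
    corrupted: ImageRecord
    expected: dict[int, dict[str, float]] = field(default_factory=dict)


def _oracle_metrics(record: ImageRecord, n: int) -> dict[str, float]:
    """Rasterization-based metric values, bypassing the sweep union."""
    boxes = propose_spray_areas(record.weed_detections(0.05), record, NozzleConfig(n))
    mask = np.zeros((record.height, record.width), dtype=bool)
    for b in boxes:
        mask[b.y_min : b.y_max, b.x_min : b.x_max] = True
    weeds = record.gt_weeds()
    hit = sum(
        bool(mask[a.box.y_min : a.box.y_max, a.box.x_min : a.box.x_max].all()) for a in weeds
    )
    assert int(mask.sum()) == rasterize_union_area(boxes, record.width, record.height)
    return {
        "wcr": 100.0 * hit / len(weeds) if weeds else float("nan"),
        "area_sprayed": 100.0 * int(mask.sum()) / record.area,
    }


def make_fixture_suite(seed: int = 0) -> list[Fixture]:
    """Small deterministic fixtures (≤ 5 boxes) with frozen expectations."""
    fixtures = []

    # one weed, detected exactly: always fully sprayed
    scene = ImageRecord(
        image_id="one-weed-one-hit", width=100, height=100,
        annotations=(Annotation(PixelBox(40, 30, 55, 45), WEED, "w0"),),
    )
    corrupted = scene.with_detections(
        [Detection(PixelBox(40, 30, 55, 45), WEED, 0.9)]
    )
    fixtures.append(Fixture("one-weed-one-hit", scene, corrupted,
                            {n: _oracle_metrics(corrupted, n) for n in (1, 2, 4)}))

    # one weed, no detections: never sprayed
    corrupted = scene.with_detections([])
    fixtures.append(Fixture("one-weed-missed",
                            replace(scene, image_id="one-weed-missed"),
                            replace(corrupted, image_id="one-weed-missed"),
                            {n: _oracle_metrics(corrupted, n) for n in (1, 2, 4)}))

    # two weeds (one detected), one crop, one spurious weed detection
    scene = ImageRecord(
        image_id="two-weeds-one-fp", width=120, height=80,
        annotations=(
            Annotation(PixelBox(10, 10, 25, 22), WEED, "w0"),
            Annotation(PixelBox(80, 50, 95, 65), WEED, "w1"),
            Annotation(PixelBox(50, 20, 70, 45), CROP, "c0"),
        ),
    )
    corrupted = scene.with_detections([
        Detection(PixelBox(11, 9, 26, 23), WEED, 0.8),
        Detection(PixelBox(30, 60, 42, 70), WEED, 0.3),
        Detection(PixelBox(50, 20, 70, 45), CROP, 0.9),
    ])
    fixtures.append(Fixture("two-weeds-one-fp", scene, corrupted,
                            {n: _oracle_metrics(corrupted, n) for n in (1, 2, 4)}))
    return fixtures
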