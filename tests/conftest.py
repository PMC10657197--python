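"""Shared fixtures and the independent pixel-mask oracle.

The oracle functions here rasterize boxes into boolean numpy masks and
answer area/containment questions by counting pixels — deliberately
naive and independent of the package's sweep-line union, so the two
routes can be compared exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

from sprayeval import Annotation, Detection, ImageRecord, NozzleConfig, PixelBox
from sprayeval.spray import propose_spray_areas


def mask_of(boxes, width: int, height: int) -> np.ndarray:
    m = np.zeros((height, width), dtype=bool)
    for b in boxes:
        m[b.y_min : b.y_max, b.x_min : b.x_max] = True
    return m


def oracle_union_area(boxes, width: int, height: int) -> int:
    return int(mask_of(boxes, width, height).sum())


def oracle_contains(gt: PixelBox, boxes, width: int, height: int) -> bool:
    m = mask_of(boxes, width, height)
    return bool(m[gt.y_min : gt.y_max, gt.x_min : gt.x_max].all())


def oracle_image_metrics(image: ImageRecord, n: int, threshold: float = 0.05):
    """(sprayed flags, union area) for one image, entirely via masks."""
    boxes = propose_spray_areas(image.weed_detections(threshold), image, NozzleConfig(n))
    m = mask_of(boxes, image.width, image.height)
    flags = [
        bool(m[a.box.y_min : a.box.y_max, a.box.x_min : a.box.x_max].all())
        for a in image.gt_weeds()
    ]
    return flags, int(m.sum())


def random_boxes(rng: np.random.Generator, width: int, height: int, count: int):
    out = []
    for _ in range(count):
        x0 = int(rng.integers(0, width))
        y0 = int(rng.integers(0, height))
        x1 = int(rng.integers(x0 + 1, width + 1))
        y1 = int(rng.integers(y0 + 1, height + 1))
        out.append(PixelBox(x0, y0, x1, y1))
    return out


def random_scene(rng: np.random.Generator, width=128, height=128,
                 n_weeds=4, n_crops=2, n_dets=4) -> ImageRecord:
    """A random annotated image with random (unrelated) weed detections."""
    anns = [
        Annotation(b, "weed", id=i)
        for i, b in enumerate(random_boxes(rng, width, height, n_weeds))
    ] + [
        Annotation(b, "crop", id=f"c{i}")
        for i, b in enumerate(random_boxes(rng, width, height, n_crops))
    ]
    dets = [
        Detection(b, "weed", confidence=float(rng.uniform(0.05, 1.0)))
        for b in random_boxes(rng, width, height, n_dets)
    ]
    return ImageRecord(
        image_id=int(rng.integers(1 << 30)), width=width, height=height,
        annotations=anns, detections=dets,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
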