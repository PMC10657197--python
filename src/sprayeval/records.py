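"""In-memory containers for annotated images.

An :class:`ImageRecord` bundles one image's dimensions, its ground-truth
annotations and its model detections for the two-class weed/crop setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from .errors import ValidationError
from .geometry import PixelBox

WEED = "weed"
CROP = "crop"
CLASS_LABELS = (WEED, CROP)

__all__ = ["WEED", "CROP", "CLASS_LABELS", "Annotation", "Detection", "ImageRecord"]


def _check_label(label: str) -> None:
    if label not in CLASS_LABELS:
        raise ValidationError(f"class_label must be one of {CLASS_LABELS}, got {label!r}")


@dataclass(frozen=True)
class Annotation:
    """A human-labelled ground-truth box."""

    box: PixelBox
    class_label: str
    id: Any = None

    def __post_init__(self) -> None:
        _check_label(self.class_label)


@dataclass(frozen=True)
class Detection:
    """A model-predicted box with a confidence score in [0, 1]."""

    box: PixelBox
    class_label: str
    confidence: float

    def __post_init__(self) -> None:
        _check_label(self.class_label)
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class ImageRecord:
    """One image: dimensions, ground truth, detections and free metadata."""

    image_id: Any
    width: int
    height: int
    annotations: tuple[Annotation, ...] = ()
    detections: tuple[Detection, ...] = ()
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"image {self.image_id!r}: dimensions must be positive "
                f"({self.width}x{self.height})"
            )
        object.__setattr__(self, "annotations", tuple(self.annotations))
        object.__setattr__(self, "detections", tuple(self.detections))
        for ann in self.annotations:
            if not ann.box.within(self.width, self.height):
                raise ValidationError(
                    f"image {self.image_id!r}: annotation {ann.id!r} box "
                    f"{ann.box.as_tuple()} outside {self.width}x{self.height}"
                )
        for det in self.detections:
            if not det.box.within(self.width, self.height):
                raise ValidationError(
                    f"image {self.image_id!r}: detection box "
                    f"{det.box.as_tuple()} outside {self.width}x{self.height}"
                )

    @property
    def area(self) -> int:
        return self.width * self.height

    def gt_weeds(self) -> tuple[Annotation, ...]:
        return tuple(a for a in self.annotations if a.class_label == WEED)

    def weed_detections(self, confidence_threshold: float = 0.0) -> tuple[Detection, ...]:
        return tuple(
            d
            for d in self.detections
            if d.class_label == WEED and d.confidence >= confidence_threshold
        )

    def with_detections(self, detections: Sequence[Detection]) -> "ImageRecord":
        return ImageRecord(
            image_id=self.image_id,
            width=self.width,
            height=self.height,
            annotations=self.annotations,
            detections=tuple(detections),
            metadata=self.metadata,
        )
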