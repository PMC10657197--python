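"""Exact integer-pixel rectangle geometry.

All boxes are axis-aligned, half-open ``[x_min, x_max) x [y_min, y_max)``
on the integer pixel grid, origin at the image's top-left corner with x
increasing rightward and y downward.  Every area in this package is an
exact pixel count, so set operations (union, intersection, containment)
admit a bit-identical brute-force rasterization check and no epsilon
tolerance appears anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["PixelBox", "SprayRegion", "union_region", "rasterize_union_area"]


@dataclass(frozen=True, order=True)
class PixelBox:
    """Half-open integer rectangle ``[x_min, x_max) x [y_min, y_max)``."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        for v in (self.x_min, self.y_min, self.x_max, self.y_max):
            if not isinstance(v, (int, np.integer)):
                raise ValidationError(f"box coordinates must be integers, got {v!r}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"box must have positive extent: "
                f"({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "PixelBox") -> int:
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        return w * h if (w > 0 and h > 0) else 0

    def intersect(self, other: "PixelBox") -> "PixelBox | None":
        """The overlap rectangle, or None when disjoint."""
        x0, y0 = max(self.x_min, other.x_min), max(self.y_min, other.y_min)
        x1, y1 = min(self.x_max, other.x_max), min(self.y_max, other.y_max)
        if x0 < x1 and y0 < y1:
            return PixelBox(x0, y0, x1, y1)
        return None

    def contains_box(self, other: "PixelBox") -> bool:
        return (
            self.x_min <= other.x_min
            and self.y_min <= other.y_min
            and other.x_max <= self.x_max
            and other.y_max <= self.y_max
        )

    def clip(self, width: int, height: int) -> "PixelBox | None":
        """Clip to image bounds ``[0, width) x [0, height)``; None if empty."""
        x0, y0 = max(self.x_min, 0), max(self.y_min, 0)
        x1, y1 = min(self.x_max, width), min(self.y_max, height)
        if x0 < x1 and y0 < y1:
            return PixelBox(x0, y0, x1, y1)
        return None

    def within(self, width: int, height: int) -> bool:
        return 0 <= self.x_min and 0 <= self.y_min and self.x_max <= width and self.y_max <= height

    def iou(self, other: "PixelBox") -> float:
        inter = self.intersection_area(other)
        if inter == 0:
            return 0.0
        return inter / (self.area + other.area - inter)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class SprayRegion:
    """Union of rectangles as a canonical disjoint-rectangle decomposition.

    ``rectangles`` are pairwise disjoint and, within each horizontal band
    of the compressed grid, maximally merged left-to-right; ``area`` is
    the exact number of pixels covered.
    """

    rectangles: tuple[PixelBox, ...]
    area: int

    def intersection_area(self, box: PixelBox) -> int:
        return sum(r.intersection_area(box) for r in self.rectangles)

    def contains(self, box: PixelBox) -> bool:
        """True iff every pixel of ``box`` is covered by the region."""
        return self.intersection_area(box) == box.area


def union_region(boxes: Sequence[PixelBox]) -> SprayRegion:
    """Exact union of rectangles by coordinate-compression sweep.

    The distinct x and y edges of the input define a compressed grid;
    each input box covers a contiguous block of grid cells, so marking
    blocks in a boolean grid and summing covered cell areas yields the
    exact pixel count of the union regardless of how boxes overlap.
    The result is independent of input order.
    """
    if not boxes:
        return SprayRegion(rectangles=(), area=0)

    xs = np.unique(np.array([e for b in boxes for e in (b.x_min, b.x_max)], dtype=np.int64))
    ys = np.unique(np.array([e for b in boxes for e in (b.y_min, b.y_max)], dtype=np.int64))
    covered = np.zeros((len(ys) - 1, len(xs) - 1), dtype=bool)
    for b in boxes:
        i0 = int(np.searchsorted(xs, b.x_min))
        i1 = int(np.searchsorted(xs, b.x_max))
        j0 = int(np.searchsorted(ys, b.y_min))
        j1 = int(np.searchsorted(ys, b.y_max))
        covered[j0:j1, i0:i1] = True

    cell_w = np.diff(xs)
    cell_h = np.diff(ys)
    area = int((covered * cell_w[np.newaxis, :] * cell_h[:, np.newaxis]).sum())

    rects: list[PixelBox] = []
    for j in range(covered.shape[0]):
        row = covered[j]
        i = 0
        while i < row.size:
            if row[i]:
                start = i
                while i < row.size and row[i]:
                    i += 1
                rects.append(PixelBox(int(xs[start]), int(ys[j]), int(xs[i]), int(ys[j + 1])))
            else:
                i += 1
    return SprayRegion(rectangles=tuple(rects), area=area)


def rasterize_union_area(boxes: Iterable[PixelBox], width: int, height: int) -> int:
    """Brute-force union area via a boolean pixel mask.

    Quadratic in image size — intended for fixture freezing and
    cross-checks, not production paths.
    """
    mask = np.zeros((height, width), dtype=bool)
    for b in boxes:
        mask[max(b.y_min, 0) : b.y_max, max(b.x_min, 0) : b.x_max] = True
    return int(mask.sum())
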