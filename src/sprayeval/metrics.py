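"""Conventional object-detection metrics: IoU, precision/recall, AP and mAP.

AP is the raw (non-interpolated) sum AP = Σ (R_k − R_{k−1})·P_k down the
confidence-ranked detection list; an optional COCO-style 101-point
interpolation is available but off by default.  mAP averages AP over the
COCO IoU-threshold grid 0.50:0.05:0.95 and over classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedMetricError
from .geometry import PixelBox
from .records import Annotation, Detection, ImageRecord, CLASS_LABELS

#: COCO-standard IoU threshold grid: 0.50, 0.55, ..., 0.95.
COCO_IOU_THRESHOLDS: tuple[float, ...] = tuple(round(0.5 + 0.05 * k, 2) for k in range(10))

__all__ = [
    "COCO_IOU_THRESHOLDS",
    "MatchResult",
    "APResult",
    "iou",
    "match_detections",
    "average_precision",
    "mean_average_precision",
]


def iou(a: PixelBox, b: PixelBox) -> float:
    """Intersection-over-union of two boxes, in pixel counts."""
    return a.iou(b)


@dataclass(frozen=True)
class MatchResult:
    """Greedy matching outcome for one image and one class.

    ``outcomes`` holds ``(confidence, is_tp)`` per detection in the
    order they were ranked (descending confidence, ties by input order).
    """

    outcomes: tuple[tuple[float, bool], ...]
    num_gt: int

    @property
    def tp(self) -> int:
        return sum(1 for _, hit in self.outcomes if hit)

    @property
    def fp(self) -> int:
        return len(self.outcomes) - self.tp

    @property
    def fn(self) -> int:
        return self.num_gt - self.tp


def match_detections(
    gts: Sequence[PixelBox],
    dets: Sequence[tuple[PixelBox, float]],
    iou_threshold: float,
) -> MatchResult:
    """Greedily match detections to ground truth within one image/class.

    Detections are taken in descending confidence (input order breaks
    ties); each is matched to the unmatched ground-truth box with the
    highest IoU at or above the threshold.  Each ground truth is used at
    most once; leftover detections are false positives and leftover
    ground truths false negatives.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][1], i))
    matched = [False] * len(gts)
    outcomes: list[tuple[float, bool]] = []
    for i in order:
        box, conf = dets[i]
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            v = box.iou(gt)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            outcomes.append((conf, True))
        else:
            outcomes.append((conf, False))
    return MatchResult(outcomes=tuple(outcomes), num_gt=len(gts))


def average_precision(
    outcomes: Sequence[tuple[float, bool]],
    total_gt: int,
    *,
    interpolation: str = "none",
) -> float:
    """AP over a confidence-ranked pooled detection list.

    ``interpolation='none'`` (default) computes the literal sum
    Σ (R_k − R_{k−1})·P_k; ``'coco101'`` averages interpolated precision
    at 101 evenly spaced recall points.
    """
    if total_gt == 0:
        raise UndefinedMetricError("average precision is undefined with zero ground-truth boxes")
    if not outcomes:
        return 0.0
    ranked = sorted(range(len(outcomes)), key=lambda i: (-outcomes[i][0], i))
    hits = np.array([outcomes[i][1] for i in ranked], dtype=float)
    tp_cum = np.cumsum(hits)
    fp_cum = np.cumsum(1.0 - hits)
    recall = tp_cum / total_gt
    precision = tp_cum / (tp_cum + fp_cum)
    if interpolation == "none":
        prev_recall = np.concatenate([[0.0], recall[:-1]])
        return float(np.sum((recall - prev_recall) * precision))
    if interpolation == "coco101":
        # precision envelope, sampled at recalls 0, 0.01, ..., 1
        env = np.maximum.accumulate(precision[::-1])[::-1]
        pts = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, pts, side="left")
        sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(sampled.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


@dataclass(frozen=True)
class APResult:
    """AP per class per IoU threshold, with per-class and overall means."""

    per_class_ap: dict[str, dict[float, float]]
    per_class_map: dict[str, float]
    map: float


def _pooled_outcomes(
    images: Sequence[ImageRecord],
    class_label: str,
    threshold: float,
) -> tuple[list[tuple[float, bool]], int]:
    pooled: list[tuple[float, bool]] = []
    total_gt = 0
    for im in images:
        gts = [a.box for a in im.annotations if a.class_label == class_label]
        dets = [(d.box, d.confidence) for d in im.detections if d.class_label == class_label]
        m = match_detections(gts, dets, threshold)
        pooled.extend(m.outcomes)
        total_gt += m.num_gt
    return pooled, total_gt


def mean_average_precision(
    images: Sequence[ImageRecord],
    iou_thresholds: Sequence[float] = COCO_IOU_THRESHOLDS,
    classes: Sequence[str] | None = None,
    *,
    interpolation: str = "none",
) -> APResult:
    """mAP over a dataset: AP pooled across images, per class per threshold.

    By default the mean runs over the classes that have at least one
    ground-truth box; explicitly requesting a class with no ground truth
    raises an undefined-metric error.
    """
    if classes is None:
        present = {a.class_label for im in images for a in im.annotations}
        classes = [c for c in CLASS_LABELS if c in present]
    if not classes:
        raise UndefinedMetricError("mAP is undefined: no ground-truth boxes of any class")
    per_class_ap: dict[str, dict[float, float]] = {}
    for cls in classes:
        per_thr: dict[float, float] = {}
        for thr in iou_thresholds:
            pooled, total_gt = _pooled_outcomes(images, cls, thr)
            per_thr[thr] = average_precision(pooled, total_gt, interpolation=interpolation)
        per_class_ap[cls] = per_thr
    per_class_map = {c: float(np.mean(list(v.values()))) for c, v in per_class_ap.items()}
    return APResult(
        per_class_ap=per_class_ap,
        per_class_map=per_class_map,
        map=float(np.mean(list(per_class_map.values()))),
    )
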