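"""Nozzle-sweep orchestration and report writing.

``run_sweep`` evaluates a dataset under each nozzle count (default
1–4), computes the spray metrics per configuration and mAP once, and
writes CSV/JSON reports plus an optional plot.  All randomness is
confined to dataset generation, so a fixed input yields byte-identical
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .errors import UndefinedMetricError, ValidationError
from .io import write_results
from .metrics import COCO_IOU_THRESHOLDS, APResult, mean_average_precision
from .records import ImageRecord
from .spray import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    DatasetSprayMetrics,
    NozzleConfig,
    evaluate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SweepReport", "run_sweep", "group_by_metadata"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a nozzle sweep."""

    nozzle_counts: tuple[int, ...] = (1, 2, 3, 4)
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    iou_thresholds: tuple[float, ...] = COCO_IOU_THRESHOLDS
    output_dir: Path | None = None
    make_plot: bool = False

    def __post_init__(self) -> None:
        if not self.nozzle_counts or any(n < 1 for n in self.nozzle_counts):
            raise ValidationError("nozzle counts must be positive")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValidationError("confidence threshold must be in [0, 1]")


@dataclass(frozen=True)
class SweepReport:
    """Per-n spray metrics plus dataset-level detection metrics."""

    rows: tuple[dict[str, Any], ...]
    spray: dict[int, DatasetSprayMetrics]
    ap: APResult


def run_sweep(images: Sequence[ImageRecord], cfg: RunConfig = RunConfig()) -> SweepReport:
    """Sweep nozzle counts over a dataset and (optionally) write reports."""
    if not images:
        raise ValidationError("empty dataset: nothing to evaluate")
    min_height = min(im.height for im in images)
    if max(cfg.nozzle_counts) > min_height:
        raise ValidationError(
            f"nozzle count {max(cfg.nozzle_counts)} exceeds minimum image height {min_height}"
        )
    n_dets = sum(len(im.detections) for im in images)
    n_kept = sum(len(im.weed_detections(cfg.confidence_threshold)) for im in images)
    logger.info(
        "sweep over n=%s: %d images, %d detections (%d weed detections kept at threshold %.2f)",
        list(cfg.nozzle_counts), len(images), n_dets, n_kept, cfg.confidence_threshold,
    )

    ap = mean_average_precision(images, cfg.iou_thresholds)
    spray: dict[int, DatasetSprayMetrics] = {}
    rows = []
    for n in cfg.nozzle_counts:
        m = evaluate_dataset(images, NozzleConfig(n), cfg.confidence_threshold)
        spray[n] = m
        logger.info(
            "n=%d: WCR %.1f%%, area sprayed %.1f%%, saving %.1f%%",
            n, m.wcr, m.area_sprayed, m.herbicide_saving,
        )
        rows.append(
            {
                "n": n,
                "wcr": m.wcr,
                "area_sprayed": m.area_sprayed,
                "herbicide_saving": m.herbicide_saving,
                "map": ap.map,
                "ap_weed": ap.per_class_map.get("weed"),
                "ap_crop": ap.per_class_map.get("crop"),
            }
        )

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(rows, out / "sweep.csv", format="csv")
        write_results(rows, out / "sweep.json", format="json")
        if cfg.make_plot:
            _plot_sweep(rows, out / "sweep.png")
    return SweepReport(rows=tuple(rows), spray=spray, ap=ap)


def _plot_sweep(rows: Sequence[Mapping[str, Any]], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ns = [r["n"] for r in rows]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ns, [r["wcr"] for r in rows], "o-", label="weed coverage rate")
    ax.plot(ns, [r["area_sprayed"] for r in rows], "s-", label="area sprayed")
    ax.set_xlabel("nozzles per image height (n)")
    ax.set_ylabel("percent")
    ax.set_xticks(ns)
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def group_by_metadata(
    images: Sequence[ImageRecord],
    key: str,
    n: int = 1,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> dict[Any, DatasetSprayMetrics | None]:
    """Spray metrics per metadata group (plus ``'__overall__'``).

    Groups with zero ground-truth weeds map to ``None`` (undefined WCR)
    rather than a silent zero.
    """
    missing = [im.image_id for im in images if key not in im.metadata]
    if missing:
        raise ValidationError(f"metadata key {key!r} missing on images: {missing}")
    groups: dict[Any, list[ImageRecord]] = {}
    for im in images:
        groups.setdefault(im.metadata[key], []).append(im)
    out: dict[Any, DatasetSprayMetrics | None] = {}
    for g, members in groups.items():
        try:
            out[g] = evaluate_dataset(members, NozzleConfig(n), confidence_threshold)
        except UndefinedMetricError:
            out[g] = None
    out["__overall__"] = evaluate_dataset(list(images), NozzleConfig(n), confidence_threshold)
    return out
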