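"""Readers and writers for COCO-JSON and YOLO-txt detection formats.

COCO bounding boxes are ``[x, y, w, h]`` floats in pixel units; they are
rounded half-away-from-zero onto the integer pixel grid and clipped to
the image.  YOLO labels are normalised ``class cx cy w h [conf]`` lines
with a JSON manifest supplying per-image pixel dimensions.  Boxes that
end up with non-positive extent are dropped with a logged warning, so
every input record is either loaded or accounted for.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .geometry import PixelBox
from .records import Annotation, Detection, ImageRecord, CLASS_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "ClassMap",
    "read_coco",
    "write_coco",
    "read_yolo",
    "write_yolo",
    "write_results",
]


@dataclass(frozen=True)
class ClassMap:
    """Maps external category ids/names onto the roles {weed, crop}."""

    mapping: Mapping[Any, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ext, role in self.mapping.items():
            if role not in CLASS_LABELS:
                raise ValidationError(f"category {ext!r} maps to unknown role {role!r}")

    def role_of(self, external: Any) -> str:
        if external in self.mapping:
            return self.mapping[external]
        # fall back to name-based matching for the common labelings
        if isinstance(external, str):
            low = external.lower()
            if "weed" in low:
                return "weed"
            if low in {"crop", "sugar beet", "sugar_beet", "beet", "sugarbeet"}:
                return "crop"
        raise ValidationError(
            f"category {external!r} has no weed/crop mapping; extend the class map"
        )


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else int(math.ceil(v - 0.5))


def _bbox_to_pixelbox(
    bbox: Sequence[float], width: int, height: int, context: str
) -> PixelBox | None:
    x, y, w, h = bbox
    raw = (_round_half_away(x), _round_half_away(y), _round_half_away(x + w), _round_half_away(y + h))
    x0, y0 = max(raw[0], 0), max(raw[1], 0)
    x1, y1 = min(raw[2], width), min(raw[3], height)
    if x0 >= x1 or y0 >= y1:
        logger.warning("dropped %s: bbox %s empty after rounding/clipping", context, list(bbox))
        return None
    if (x0, y0, x1, y1) != raw:
        logger.warning("clipped %s: bbox %s to %s", context, list(bbox), (x0, y0, x1, y1))
    return PixelBox(x0, y0, x1, y1)


def read_coco(
    gt_path: str | Path,
    det_path: str | Path | None = None,
    class_map: ClassMap | None = None,
) -> list[ImageRecord]:
    """Load COCO ground truth and (optionally) COCO results-format detections.

    Detections are attached by ``image_id``; images absent from the
    results file get empty detection lists.
    """
    class_map = class_map or ClassMap()
    with open(gt_path) as fh:
        gt = json.load(fh)
    cat_role = {c["id"]: class_map.role_of(c.get("name", c["id"])) for c in gt.get("categories", [])}

    images: dict[Any, dict] = {im["id"]: im for im in gt["images"]}
    anns_by_image: dict[Any, list[Annotation]] = {iid: [] for iid in images}
    for ann in gt.get("annotations", []):
        im = images.get(ann["image_id"])
        if im is None:
            raise ValidationError(f"annotation {ann.get('id')!r} references unknown image "
                                  f"{ann['image_id']!r}")
        if ann["category_id"] not in cat_role:
            raise ValidationError(f"annotation {ann.get('id')!r} uses unknown category "
                                  f"{ann['category_id']!r}")
        box = _bbox_to_pixelbox(
            ann["bbox"], im["width"], im["height"], f"annotation {ann.get('id')!r}"
        )
        if box is not None:
            anns_by_image[im["id"]].append(
                Annotation(box=box, class_label=cat_role[ann["category_id"]], id=ann.get("id"))
            )

    dets_by_image: dict[Any, list[Detection]] = {iid: [] for iid in images}
    if det_path is not None:
        with open(det_path) as fh:
            dets = json.load(fh)
        for k, det in enumerate(dets):
            im = images.get(det["image_id"])
            if im is None:
                raise ValidationError(f"detection #{k} references unknown image "
                                      f"{det['image_id']!r}")
            if det["category_id"] not in cat_role:
                raise ValidationError(f"detection #{k} uses unknown category "
                                      f"{det['category_id']!r}")
            box = _bbox_to_pixelbox(det["bbox"], im["width"], im["height"], f"detection #{k}")
            if box is not None:
                dets_by_image[im["id"]].append(
                    Detection(
                        box=box,
                        class_label=cat_role[det["category_id"]],
                        confidence=float(det["score"]),
                    )
                )

    records = []
    for iid, im in images.items():
        records.append(
            ImageRecord(
                image_id=iid,
                width=im["width"],
                height=im["height"],
                annotations=tuple(anns_by_image[iid]),
                detections=tuple(dets_by_image[iid]),
                metadata={k: v for k, v in im.items()
                          if k not in {"id", "width", "height"}},
            )
        )
    return records


_COCO_CATEGORIES = [{"id": 1, "name": "weed"}, {"id": 2, "name": "crop"}]
_ROLE_TO_CAT = {"weed": 1, "crop": 2}


def write_coco(
    records: Sequence[ImageRecord],
    gt_path: str | Path,
    det_path: str | Path | None = None,
) -> None:
    """Serialize records as COCO ground truth plus results-format detections."""
    images, annotations, detections = [], [], []
    ann_id = 1
    for rec in records:
        entry = {"id": rec.image_id, "width": rec.width, "height": rec.height}
        entry.update({k: v for k, v in rec.metadata.items() if k not in entry})
        images.append(entry)
        for a in rec.annotations:
            annotations.append(
                {
                    "id": a.id if a.id is not None else ann_id,
                    "image_id": rec.image_id,
                    "category_id": _ROLE_TO_CAT[a.class_label],
                    "bbox": [a.box.x_min, a.box.y_min, a.box.width, a.box.height],
                    "area": a.box.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
        for d in rec.detections:
            detections.append(
                {
                    "image_id": rec.image_id,
                    "category_id": _ROLE_TO_CAT[d.class_label],
                    "bbox": [d.box.x_min, d.box.y_min, d.box.width, d.box.height],
                    "score": d.confidence,
                }
            )
    with open(gt_path, "w") as fh:
        json.dump(
            {"images": images, "annotations": annotations, "categories": _COCO_CATEGORIES},
            fh,
            indent=1,
            sort_keys=True,
        )
    if det_path is not None:
        with open(det_path, "w") as fh:
            json.dump(detections, fh, indent=1, sort_keys=True)


def _yolo_line_to_box(
    parts: Sequence[float], width: int, height: int, where: str
) -> PixelBox | None:
    cx, cy, w, h = parts
    for v in (cx, cy, w, h):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{where}: normalised coordinate {v} outside [0, 1]")
    box = (
        _round_half_away((cx - w / 2) * width),
        _round_half_away((cy - h / 2) * height),
        _round_half_away((cx + w / 2) * width),
        _round_half_away((cy + h / 2) * height),
    )
    x0, y0 = max(box[0], 0), max(box[1], 0)
    x1, y1 = min(box[2], width), min(box[3], height)
    if x0 >= x1 or y0 >= y1:
        logger.warning("dropped %s: degenerate box after denormalisation", where)
        return None
    return PixelBox(x0, y0, x1, y1)


def read_yolo(
    labels_dir: str | Path,
    images_manifest: str | Path,
    class_map: ClassMap | None = None,
    *,
    detections: bool = False,
) -> list[ImageRecord]:
    """Load YOLO-txt labels using a JSON manifest of image dimensions.

    The manifest is a list of ``{"image_id", "width", "height"}`` objects;
    ``<labels_dir>/<image_id>.txt`` holds that image's boxes.  With
    ``detections=True`` a sixth confidence column is required and the
    boxes are loaded as detections instead of annotations.
    """
    class_map = class_map or ClassMap({0: "weed", 1: "crop"})
    labels_dir = Path(labels_dir)
    with open(images_manifest) as fh:
        manifest = json.load(fh)
    records = []
    for entry in manifest:
        iid, width, height = entry["image_id"], entry["width"], entry["height"]
        path = labels_dir / f"{iid}.txt"
        anns: list[Annotation] = []
        dets: list[Detection] = []
        if path.exists():
            for lineno, line in enumerate(path.read_text().splitlines(), start=1):
                if not line.strip():
                    continue
                parts = line.split()
                where = f"{path}:{lineno}"
                role = class_map.role_of(int(parts[0]))
                box = _yolo_line_to_box([float(p) for p in parts[1:5]], width, height, where)
                if box is None:
                    continue
                if detections:
                    if len(parts) < 6:
                        raise ValidationError(f"{where}: missing confidence column")
                    dets.append(Detection(box=box, class_label=role, confidence=float(parts[5])))
                else:
                    anns.append(Annotation(box=box, class_label=role, id=f"{iid}:{lineno}"))
        records.append(
            ImageRecord(
                image_id=iid,
                width=width,
                height=height,
                annotations=tuple(anns),
                detections=tuple(dets),
            )
        )
    return records


def write_yolo(records: Sequence[ImageRecord], labels_dir: str | Path,
               manifest_path: str | Path, *, detections: bool = False) -> None:
    """Write annotations (or detections) as YOLO txt plus a dimensions manifest."""
    role_to_idx = {"weed": 0, "crop": 1}
    labels_dir = Path(labels_dir)
    labels_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        manifest.append({"image_id": rec.image_id, "width": rec.width, "height": rec.height})
        lines = []
        items: Iterable = rec.detections if detections else rec.annotations
        for item in items:
            b = item.box
            cx = (b.x_min + b.x_max) / 2 / rec.width
            cy = (b.y_min + b.y_max) / 2 / rec.height
            w = b.width / rec.width
            h = b.height / rec.height
            cols = [str(role_to_idx[item.class_label]),
                    f"{cx:.6f}", f"{cy:.6f}", f"{w:.6f}", f"{h:.6f}"]
            if detections:
                cols.append(f"{item.confidence:.6f}")
            lines.append(" ".join(cols))
        (labels_dir / f"{rec.image_id}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


RESULT_COLUMNS = ["n", "wcr", "area_sprayed", "herbicide_saving", "map", "ap_weed", "ap_crop"]


def write_results(rows: Sequence[Mapping[str, Any]], path: str | Path,
                  format: str = "csv") -> None:
    """Write sweep results with a stable column order; deterministic output.

    Each row is a mapping with any subset of ``RESULT_COLUMNS`` (missing
    entries become NA).  ``format`` is ``csv`` or ``json``.
    """
    frame = pd.DataFrame(list(rows))
    cols = [c for c in RESULT_COLUMNS if c in frame.columns] + [
        c for c in frame.columns if c not in RESULT_COLUMNS
    ]
    frame = frame[cols]
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "json":
        frame.to_json(path, orient="records", indent=1)
    else:
        raise ValidationError(f"unknown results format {format!r}")
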