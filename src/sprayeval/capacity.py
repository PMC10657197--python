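"""Sprayer capacity arithmetic: cameras along the boom and frame rates.

A camera mounted on the boom images a fixed ground footprint (default
670 mm × 380 mm, a 1.8:1 sensor ~500 mm above the canopy).  Covering a
24 m boom takes ``ceil(boom / across-boom edge)`` cameras, and driving
at speed v each camera must capture ``v / along-travel edge`` frames per
second so no ground is missed.  The aggregate frame rate — the load the
detection pipeline must sustain — is the product of the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

from .errors import ValidationError

MPH_TO_MPS = 0.44704  # exact statutory factor
MPH_TO_KMPH = 1.609344

LONG_EDGE_ALONG_BOOM = "long-edge-along-boom"
SHORT_EDGE_ALONG_BOOM = "short-edge-along-boom"

__all__ = [
    "SprayerGeometry",
    "required_cameras",
    "required_fps_per_camera",
    "aggregate_fps",
    "mph_to_mps",
    "mph_to_kmph",
    "LONG_EDGE_ALONG_BOOM",
    "SHORT_EDGE_ALONG_BOOM",
]


@dataclass(frozen=True)
class SprayerGeometry:
    """Boom, camera footprint and travel speed for capacity sizing."""

    boom_length_mm: float = 24_000.0
    long_edge_mm: float = 670.0
    short_edge_mm: float = 380.0
    speed_mps: float = 6.7
    orientation: str = SHORT_EDGE_ALONG_BOOM

    def __post_init__(self) -> None:
        for name in ("boom_length_mm", "long_edge_mm", "short_edge_mm", "speed_mps"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.orientation not in (LONG_EDGE_ALONG_BOOM, SHORT_EDGE_ALONG_BOOM):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def along_boom_mm(self) -> float:
        if self.orientation == LONG_EDGE_ALONG_BOOM:
            return self.long_edge_mm
        return self.short_edge_mm

    @property
    def along_travel_mm(self) -> float:
        if self.orientation == LONG_EDGE_ALONG_BOOM:
            return self.short_edge_mm
        return self.long_edge_mm


def required_cameras(geom: SprayerGeometry) -> int:
    """Cameras needed to cover the boom: ceiling, so no gap is left."""
    return ceil(geom.boom_length_mm / geom.along_boom_mm)


def required_fps_per_camera(geom: SprayerGeometry) -> float:
    """Frames per second per camera so consecutive footprints abut (no overlap)."""
    return geom.speed_mps / (geom.along_travel_mm / 1000.0)


def aggregate_fps(geom: SprayerGeometry) -> float:
    """Total frames per second across all cameras on the boom."""
    return required_cameras(geom) * required_fps_per_camera(geom)


def mph_to_mps(v: float) -> float:
    if v < 0:
        raise ValidationError("speed must be >= 0")
    return v * MPH_TO_MPS


def mph_to_kmph(v: float) -> float:
    if v < 0:
        raise ValidationError("speed must be >= 0")
    return v * MPH_TO_KMPH
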