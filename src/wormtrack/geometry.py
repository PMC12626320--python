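"""Axis-aligned bounding boxes, coordinate conventions, and overlap.

Coordinate frame: origin at the top-left of the image, x rightward, y
downward, continuous (sub-pixel) coordinates. Boxes are closed real
intervals, not integer pixel grids. The canonical in-memory form is
center-width-height; corner forms exist only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidBoxError, MissingCalibrationError

__all__ = ["BoundingBox", "Detection", "iou", "convert_box", "aspect_ratio", "CONVENTIONS"]

#: Recognized box coordinate conventions.
#:
#: - ``center-wh``: (cx, cy, w, h) in pixels (canonical form)
#: - ``corner-xyxy``: (x1, y1, x2, y2) opposite corners in pixels
#: - ``corner-xywh``: (x_left, y_top, w, h) in pixels
#: - ``normalized-center-wh``: (cx, cy, w, h) as fractions of image size
CONVENTIONS = ("center-wh", "corner-xyxy", "corner-xywh", "normalized-center-wh")


@dataclass(frozen=True)
class BoundingBox:
    """One axis-aligned box in center-width-height form (pixels)."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box width/height must be positive, got w={self.w}, h={self.h}")

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_xyxy(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    @classmethod
    def from_xyxy(cls, x1: float, y1: float, x2: float, y2: float) -> "BoundingBox":
        return cls(cx=(x1 + x2) / 2.0, cy=(y1 + y2) / 2.0, w=x2 - x1, h=y2 - y1)


@dataclass(frozen=True)
class Detection:
    """One detector output: a box with a confidence score on one frame."""

    box: BoundingBox
    score: float
    frame: int
    class_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.frame < 0:
            raise ValueError(f"frame index must be >= 0, got {self.frame}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 1 for identical, 0 for disjoint."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def aspect_ratio(box: BoundingBox) -> float:
    """Width-over-height ratio r = w/h of one box."""
    return box.w / box.h


def convert_box(
    box: tuple[float, float, float, float] | BoundingBox,
    from_convention: str,
    to_convention: str,
    image_size: tuple[float, float] | None = None,
) -> tuple[float, float, float, float]:
    """Re-express a box tuple in another coordinate convention.

    Parameters
    ----------
    box
        Four numbers interpreted per ``from_convention`` (a :class:`BoundingBox`
        is accepted and read as center-wh).
    image_size
        ``(width, height)`` in pixels; required whenever either convention is
        ``normalized-center-wh``.

    Returns
    -------
    Four numbers in ``to_convention``. Round-trips are exact up to floating
    tolerance.
    """
    for conv in (from_convention, to_convention):
        if conv not in CONVENTIONS:
            raise ValueError(f"unknown convention {conv!r}; expected one of {CONVENTIONS}")
    if isinstance(box, BoundingBox):
        values = (box.cx, box.cy, box.w, box.h)
        from_convention = "center-wh"
    else:
        values = tuple(float(v) for v in box)

    needs_size = "normalized-center-wh" in (from_convention, to_convention)
    if needs_size and image_size is None:
        raise MissingCalibrationError(
            "normalized-coordinate conversion requires image_size=(width, height)"
        )

    # normalize to canonical center-wh in pixels
    a, b, c, d = values
    if from_convention == "center-wh":
        cx, cy, w, h = a, b, c, d
    elif from_convention == "corner-xyxy":
        cx, cy, w, h = (a + c) / 2.0, (b + d) / 2.0, c - a, d - b
    elif from_convention == "corner-xywh":
        cx, cy, w, h = a + c / 2.0, b + d / 2.0, c, d
    else:  # normalized-center-wh
        iw, ih = image_size  # type: ignore[misc]
        cx, cy, w, h = a * iw, b * ih, c * iw, d * ih

    if to_convention == "center-wh":
        return (cx, cy, w, h)
    if to_convention == "corner-xyxy":
        return (cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)
    if to_convention == "corner-xywh":
        return (cx - w / 2.0, cy - h / 2.0, w, h)
    iw, ih = image_size  # type: ignore[misc]
    return (cx / iw, cy / ih, w / iw, h / ih)
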