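"""Core value types shared by every stage of the pipeline.

Coordinate conventions, fixed once for the whole package:

* pixel coordinates are 0-based, ``x`` rightward (columns), ``y`` downward
  (rows);
* bounding boxes are half-open integer rectangles
  ``[x_min, x_max) x [y_min, y_max)``, so ``width = x_max - x_min`` and a box
  drawn on a pixel grid covers exactly ``width * height`` pixels;
* circles have continuous centers and a positive radius in pixels.

The 1-based inclusive convention used by Pascal-VOC XML exists only at the
XML import/export boundary (see :mod:`fundlocate.annotations`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BoundingBox", "CircleProposal", "FundusImage", "ValidationError"]


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open: ``[x_min, x_max) x [y_min, y_max)``."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
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

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) of the box, continuous coordinates."""
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def clipped(self, height: int, width: int) -> "BoundingBox":
        """Intersect with the image frame ``[0, width) x [0, height)``."""
        return BoundingBox(
            max(0, self.x_min),
            max(0, self.y_min),
            min(width, self.x_max),
            min(height, self.y_max),
        )

    def contains_point(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass(frozen=True)
class CircleProposal:
    """A circular optic-disc (or retina) hypothesis: center (cx, cy), radius r."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValidationError(f"circle radius must be positive, got {self.r}")

    def to_box(self, height: int | None = None, width: int | None = None) -> BoundingBox:
        """Tight square box of the circle, optionally clipped to an image frame."""
        box = BoundingBox(
            int(np.floor(self.cx - self.r)),
            int(np.floor(self.cy - self.r)),
            int(np.ceil(self.cx + self.r)),
            int(np.ceil(self.cy + self.r)),
        )
        if height is not None and width is not None:
            box = box.clipped(height, width)
        return box


@dataclass
class FundusImage:
    """An 8-bit RGB retinal fundus raster with identity and size metadata."""

    pixels: np.ndarray
    image_id: str = ""
    original_size: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValidationError(f"image too small: {px.shape[:2]} (minimum 32x32)")
        if px.dtype != np.uint8:
            raise ValidationError(f"expected uint8 pixels, got {px.dtype}")
        self.pixels = px
        if self.original_size is None:
            self.original_size = (px.shape[0], px.shape[1])

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def grayscale(self) -> np.ndarray:
        """Luminance (0.299 R + 0.587 G + 0.114 B) as float64 in [0, 255]."""
        return (
            0.299 * self.pixels[..., 0].astype(np.float64)
            + 0.587 * self.pixels[..., 1]
            + 0.114 * self.pixels[..., 2]
        )
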