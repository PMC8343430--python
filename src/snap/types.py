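"""Core domain types shared across the pipeline.

Coordinate convention used everywhere: pixel coordinates are 0-based with
the origin at the top-left corner, x pointing right and y pointing down.
Boxes are half-open: a box covers pixels with x_min <= x < x_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BoundingBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def iou(self, other: "BoundingBox") -> float:
        ix = max(0.0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0.0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    score: float
    label: str = "nodule"

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class AnnotatedImage:
    """An RGB raster with its nodule boxes and optional taproot mask."""

    image_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    boxes: list[BoundingBox] = field(default_factory=list)
    taproot_mask: np.ndarray | None = None  # (H, W) in {0, 1}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        h, w = px.shape[:2]
        for b in self.boxes:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h:
                raise ValueError(f"box {b} outside {w}x{h} raster")
        if self.taproot_mask is not None and self.taproot_mask.shape[:2] != (h, w):
            raise ValueError(
                f"mask shape {self.taproot_mask.shape} != image shape {(h, w)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]
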