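"""Axis-aligned pixel rectangles and the distance/overlap primitives.

Coordinate convention, used everywhere in the package: origin at the
top-left corner of the image or page, ``y`` grows downward, and boxes are
half-open pixel intervals ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BBox", "bbox_min_distance", "bbox_overlaps", "bbox_union"]


@dataclass(frozen=True, order=True)
class BBox:
    """Axis-aligned rectangle, half-open in both axes.

    Parameters
    ----------
    x_min, y_min : int
        Top-left corner (inclusive). Must be >= 0.
    x_max, y_max : int
        Bottom-right corner (exclusive). Must be strictly greater than the
        corresponding minimum.
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"negative origin in {self!r}")
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValueError(f"empty or inverted box {self!r}")

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
        """(x, y) midpoint of the closed rectangle."""
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        """Half-open membership test for a point."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    def to_list(self) -> list[int]:
        """JSON serialization form: ``[x_min, y_min, x_max, y_max]``."""
        return [self.x_min, self.y_min, self.x_max, self.y_max]

    @classmethod
    def from_list(cls, seq) -> "BBox":
        x0, y0, x1, y1 = seq
        return cls(int(x0), int(y0), int(x1), int(y1))


def bbox_min_distance(a: BBox, b: BBox) -> float:
    """Minimum Euclidean distance between two closed rectangles.

    Returns 0 when the rectangles intersect or touch. Symmetric in its
    arguments. The closed-boundary convention means boxes that are adjacent
    in the half-open sense (sharing an edge coordinate) are at distance 0.
    """
    # Gap along each axis between the closed intervals [min, max].
    dx = max(0, a.x_min - b.x_max, b.x_min - a.x_max)
    dy = max(0, a.y_min - b.y_max, b.y_min - a.y_max)
    return math.hypot(dx, dy)


def bbox_overlaps(a: BBox, b: BBox) -> bool:
    """True iff the half-open pixel sets of the two boxes intersect."""
    return (
        a.x_min < b.x_max
        and b.x_min < a.x_max
        and a.y_min < b.y_max
        and b.y_min < a.y_max
    )


def bbox_union(a: BBox, b: BBox) -> BBox:
    """Smallest box containing both inputs. Associative and commutative."""
    return BBox(
        min(a.x_min, b.x_min),
        min(a.y_min, b.y_min),
        max(a.x_max, b.x_max),
        max(a.y_max, b.y_max),
    )
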