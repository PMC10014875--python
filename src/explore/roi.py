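"""Axis-aligned rectangular regions of interest.

Coordinates are 0-based pixel indices and half-open: a region covers the
pixel block ``[x0, x1) x [y0, y1)``, matching numpy slicing semantics so
``frame[y0:y1, x0:x1]`` extracts exactly the region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import BoundsError


@dataclass(frozen=True)
class RegionOfInterest:
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise BoundsError(
                f"degenerate or negative ROI ({self.x0},{self.y0},{self.x1},{self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def within(self, width: int, height: int) -> bool:
        """Whether the region lies inside a ``width x height`` frame."""
        return self.x1 <= width and self.y1 <= height

    def slice(self) -> tuple[slice, slice]:
        """(row, column) slices extracting this region from a frame array."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def to_list(self) -> list[int]:
        return [self.x0, self.y0, self.x1, self.y1]

    @classmethod
    def from_sequence(cls, seq) -> "RegionOfInterest":
        x0, y0, x1, y1 = (int(v) for v in seq)
        return cls(x0, y0, x1, y1)
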