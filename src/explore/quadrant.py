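"""Habituation-phase roaming analysis over arena quadrants.

Before presenting objects, experimenters check that the animal shows no
spatial preference in the empty arena. The animal is located per frame
by mean pixel intensity: the arena is split into a 2x2 grid and the
quadrant whose mean intensity deviates most from a reference (an
empty-arena frame, or the per-pixel temporal median of the video) is
taken as the animal's quadrant. From the per-frame quadrant track the
occupancy time per quadrant and the number of inter-quadrant transitions
are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import BoundsError, ConsistencyError
from .roi import RegionOfInterest
from .video_io import FrameStack

#: Sentinel quadrant index for frames where no deviation clears the noise floor.
NOT_LOCATED = -1

#: Mean-intensity deviation below which a frame counts as "not located".
DEFAULT_NOISE_FLOOR = 1.0

#: Frames a new quadrant must persist before a transition is counted.
DEFAULT_MIN_DWELL = 3


def quadrant_grid(arena: RegionOfInterest) -> list[RegionOfInterest]:
    """2x2 partition of the arena, row-major; extra pixel right/bottom."""
    if arena.width < 2 or arena.height < 2:
        raise BoundsError("arena must be at least 2x2 pixels")
    mx = arena.x0 + arena.width // 2
    my = arena.y0 + arena.height // 2
    return [
        RegionOfInterest(arena.x0, arena.y0, mx, my),
        RegionOfInterest(mx, arena.y0, arena.x1, my),
        RegionOfInterest(arena.x0, my, mx, arena.y1),
        RegionOfInterest(mx, my, arena.x1, arena.y1),
    ]


def _quadrant_means(frame: np.ndarray, quadrants: list[RegionOfInterest]) -> np.ndarray:
    gray = frame.astype(np.float64)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    return np.array([gray[q.slice()].mean() for q in quadrants])


def locate_by_intensity(
    frame: np.ndarray,
    reference: np.ndarray,
    quadrants: list[RegionOfInterest],
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    use_reference: bool = True,
) -> int:
    """Quadrant of the largest mean-intensity deviation from reference.

    Ties break toward the lowest quadrant index; if no quadrant deviates
    more than ``noise_floor``, returns :data:`NOT_LOCATED`. With
    ``use_reference=False`` the raw quadrant means are compared instead
    (brightest-or-darkest-quadrant heuristic is then the caller's
    responsibility; the deviation rule is the default).
    """
    if frame.shape[:2] != reference.shape[:2]:
        raise ConsistencyError("frame and reference dimensions differ")
    means = _quadrant_means(frame, quadrants)
    if use_reference:
        deviation = np.abs(means - _quadrant_means(reference, quadrants))
    else:
        deviation = means
    best = int(np.argmax(deviation))  # argmax -> lowest index on ties
    if use_reference and deviation[best] < noise_floor:
        return NOT_LOCATED
    return best


def median_reference(stack: FrameStack, sample_every: int = 5) -> np.ndarray:
    """Per-pixel temporal median as an empty-arena stand-in."""
    frames = stack.frames[::sample_every].astype(np.float64)
    if frames.ndim == 4:
        frames = frames.mean(axis=3)
    return np.median(frames, axis=0)


@dataclass
class QuadrantTrack:
    """Per-frame quadrant index (0..3 or NOT_LOCATED) for one video."""

    video_id: str
    quadrants: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.quadrants = np.asarray(self.quadrants, dtype=np.int64)
        bad = (self.quadrants < NOT_LOCATED) | (self.quadrants > 3)
        if bad.any():
            raise ConsistencyError("quadrant indices must be in {-1, 0..3}")
        if self.fps <= 0:
            raise ConsistencyError("fps must be positive")

    def __len__(self) -> int:
        return len(self.quadrants)


def track_quadrants(
    stack: FrameStack,
    arena: RegionOfInterest | None = None,
    reference: np.ndarray | None = None,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> QuadrantTrack:
    """Locate the animal in every frame of a video."""
    arena = arena or RegionOfInterest(0, 0, stack.width, stack.height)
    if not arena.within(stack.width, stack.height):
        raise BoundsError("arena outside video frame")
    quadrants = quadrant_grid(arena)
    if reference is None:
        reference = median_reference(stack)
    track = np.empty(len(stack), dtype=np.int64)
    for i in range(len(stack)):
        track[i] = locate_by_intensity(
            stack.frames[i], reference, quadrants, noise_floor=noise_floor
        )
    return QuadrantTrack(stack.source_id, track, stack.fps)


def occupancy_times(track: QuadrantTrack) -> dict[int, Fraction]:
    """Seconds per quadrant; key NOT_LOCATED collects unlocated frames.

    Values are exact rationals; they sum to the video duration.
    """
    fps = Fraction(track.fps).limit_denominator(10**6)
    out = {q: Fraction(0) for q in (0, 1, 2, 3, NOT_LOCATED)}
    values, counts = np.unique(track.quadrants, return_counts=True)
    for v, c in zip(values, counts):
        out[int(v)] = Fraction(int(c)) / fps
    return out


def transition_count(track: QuadrantTrack, min_dwell_frames: int = DEFAULT_MIN_DWELL) -> int:
    """Debounced count of quadrant changes.

    A change counts only once the new quadrant has persisted for
    ``min_dwell_frames`` consecutive frames; not-located frames are
    transparent (the animal is assumed to stay where it was).
    """
    if min_dwell_frames < 1:
        raise ConsistencyError("min_dwell_frames must be >= 1")
    seq = [int(q) for q in track.quadrants if q != NOT_LOCATED]
    if not seq:
        return 0
    count = 0
    current = seq[0]
    i = 1
    while i < len(seq):
        q = seq[i]
        if q == current:
            i += 1
            continue
        run = 1  # how long the candidate quadrant persists (capped at min_dwell)
        while i + run < len(seq) and seq[i + run] == q and run < min_dwell_frames:
            run += 1
        if run >= min_dwell_frames:
            count += 1
            current = q
        i += run
    return count
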