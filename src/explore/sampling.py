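"""Representative video selection and scoring-video assembly.

To label training data efficiently, a user does not score whole videos:
``n`` representative videos are picked (k-means over coarse appearance
features, one random pick per cluster — this captures e.g. slight camera
shifts between sessions), and from each minute of each selected video a
contiguous fragment is cut so that the merged "scoring video" lasts the
requested ``j`` minutes. With videos of ``i`` minutes the fragment is
the fraction ``j / (i * n)`` of each minute, which requires ``j < i*n``.
Fragments stay temporally contiguous so a human can scroll and score
them efficiently, and an index map records where every merged frame came
from so labels can be mapped back to source frames exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import BoundsError, ConsistencyError, ConstraintError
from .video_io import FrameStack


def video_feature(stack: FrameStack, grid: int = 16) -> np.ndarray:
    """Appearance feature: temporal-mean frame, grayscale, ``grid x grid``.

    The downsampling is an exact block mean over an even partition of the
    frame (cell edges at ``i * H // g``), flattened to length ``grid**2``.
    """
    if len(stack) == 0:
        raise ConsistencyError("empty frame stack")
    mean_frame = stack.frames.astype(np.float64).mean(axis=(0, 3))  # H x W, gray
    h, w = mean_frame.shape
    if grid > min(h, w):
        raise ConsistencyError(f"grid {grid} exceeds frame size {w}x{h}")
    rows = [h * i // grid for i in range(grid + 1)]
    cols = [w * i // grid for i in range(grid + 1)]
    out = np.empty(grid * grid, dtype=np.float64)
    for r in range(grid):
        for c in range(grid):
            cell = mean_frame[rows[r] : rows[r + 1], cols[c] : cols[c + 1]]
            out[r * grid + c] = cell.mean()
    return out


def cluster_videos(
    features: np.ndarray, n: int, seed: int = 0
) -> tuple[list[int], np.ndarray]:
    """k-means with k = n; one seeded random representative per cluster.

    Returns ``(representatives, cluster_assignment)``; representatives
    are indices into the feature rows, ordered by cluster id.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ConsistencyError("features must be a 2-D array (videos x feature)")
    if n > len(features):
        raise ConsistencyError(f"cannot form {n} clusters from {len(features)} videos")
    km = KMeans(n_clusters=n, random_state=seed, n_init=10)
    assignment = km.fit_predict(features)
    rng = np.random.default_rng([seed, 0xC1])
    reps = []
    for cluster in range(n):
        members = np.flatnonzero(assignment == cluster)
        reps.append(int(rng.choice(members)))
    return reps, assignment


@dataclass(frozen=True)
class Segment:
    video_index: int
    start_frame: int
    end_frame: int  # half-open

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class SamplingPlan:
    """The (n, i, j) scoring-video construction."""

    n: int
    i: int
    j: int
    fps: float
    segments: list[Segment]

    @property
    def fraction(self) -> Fraction:
        """Exact per-minute fraction j / (i*n); fraction * i * n == j."""
        return Fraction(self.j, self.i * self.n)

    @property
    def total_frames(self) -> int:
        return sum(s.length for s in self.segments)


def build_scoring_plan(
    n: int, i: int, j: int, fps: float,
    seed: int | None = None,
) -> SamplingPlan:
    """Plan one contiguous fragment per (video, minute).

    Each fragment has ``round(fraction * 60 * fps)`` frames (round half
    up) and starts at the minute boundary, or at a seeded random offset
    within the minute when ``seed`` is given. Totals can differ from
    ``j`` minutes by less than one frame per segment due to rounding.
    """
    if min(n, i, j) < 1:
        raise ConstraintError("n, i, j must all be >= 1")
    if j >= i * n:
        raise ConstraintError(
            f"target minutes j={j} must be smaller than i*n={i * n}"
        )
    fraction = Fraction(j, i * n)
    frames_per_minute = int(round(60 * fps))
    seg_len = int(np.floor(fraction * 60 * Fraction(fps).limit_denominator(10**6) + Fraction(1, 2)))
    rng = None if seed is None else np.random.default_rng([seed, 0x5A])
    segments = []
    for v in range(n):
        for m in range(i):
            start = m * frames_per_minute
            if rng is not None and frames_per_minute > seg_len:
                start += int(rng.integers(0, frames_per_minute - seg_len + 1))
            segments.append(Segment(v, start, start + seg_len))
    return SamplingPlan(n=n, i=i, j=j, fps=fps, segments=segments)


@dataclass
class IndexMap:
    """merged frame index -> (source video id, source frame index)."""

    video_ids: list[str]
    entries: np.ndarray  # (M, 2): video_index, source_frame

    def __len__(self) -> int:
        return len(self.entries)

    def source_of(self, merged_index: int) -> tuple[str, int]:
        v, f = self.entries[merged_index]
        return self.video_ids[int(v)], int(f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "merged_idx": np.arange(len(self.entries)),
                "video_id": [self.video_ids[int(v)] for v in self.entries[:, 0]],
                "src_idx": self.entries[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path) -> "IndexMap":
        table = pd.read_csv(path)
        ids = list(dict.fromkeys(table["video_id"].astype(str)))
        lookup = {v: k for k, v in enumerate(ids)}
        entries = np.stack(
            [table["video_id"].astype(str).map(lookup).to_numpy(),
             table["src_idx"].to_numpy()], axis=1
        )
        return cls(ids, entries.astype(np.int64))


def assemble_scoring_video(
    plan: SamplingPlan, stacks: list[FrameStack]
) -> tuple[FrameStack, IndexMap]:
    """Concatenate the planned segments into the manual-scoring video."""
    if not stacks:
        raise ConsistencyError("no videos given")
    parts, entries = [], []
    for seg in plan.segments:
        if seg.video_index >= len(stacks):
            raise BoundsError(f"plan references video {seg.video_index}")
        stack = stacks[seg.video_index]
        if seg.end_frame > len(stack):
            raise BoundsError(
                f"segment [{seg.start_frame},{seg.end_frame}) out of range for "
                f"{stack.source_id} ({len(stack)} frames)"
            )
        parts.append(stack.frames[seg.start_frame : seg.end_frame])
        entries.append(
            np.stack(
                [np.full(seg.length, seg.video_index),
                 np.arange(seg.start_frame, seg.end_frame)], axis=1
            )
        )
    merged = FrameStack(
        np.concatenate(parts), stacks[0].fps, source_id="scoring_video"
    )
    index_map = IndexMap(
        [s.source_id for s in stacks], np.concatenate(entries).astype(np.int64)
    )
    return merged, index_map
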