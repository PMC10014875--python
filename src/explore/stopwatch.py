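"""From per-frame predictions to exploration times and the DI.

Exploration time is a frame count divided by the frame rate: every frame
hard-classified as class c contributes 1/fps seconds to c. Scores are
also broken into 1-minute segments (the unit at which methods are
compared against a human rater).

The discrimination index (DI) quantifies object preference in percent:

    DI_acq  = t_o1' / (t_o1 + t_o1') * 100      (acquisition session)
    DI_test = t_o1  / (t_o1 + t_o2 ) * 100      (testing session)

where t_o1 and t_o1' are the times on the two identical objects in the
acquisition session, and in the testing session t_o1 is the familiar and
t_o2 the novel object. 50% is chance level. With zero combined time the
DI is undefined (such animals are typically excluded from analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, UndefinedDIError
from .labeling import ClassScheme

SEGMENT_SECONDS = 60


@dataclass
class PredictionTrack:
    """Per-frame class probabilities and hard classes for one video."""

    video_id: str
    probabilities: np.ndarray  # (N, K)
    hard_classes: np.ndarray   # (N,)
    fps: float

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        self.hard_classes = np.asarray(self.hard_classes, dtype=np.int64)
        if self.probabilities.ndim != 2:
            raise ConsistencyError("probabilities must be (N, K)")
        if len(self.probabilities) != len(self.hard_classes):
            raise ConsistencyError("probability and hard-class lengths differ")
        if self.fps <= 0:
            raise ConsistencyError("fps must be positive")

    def __len__(self) -> int:
        return len(self.hard_classes)

    @property
    def K(self) -> int:
        return self.probabilities.shape[1]

    @classmethod
    def from_hard(cls, video_id: str, classes: np.ndarray, K: int, fps: float):
        """A degenerate track with one-hot probabilities (e.g. ground truth)."""
        classes = np.asarray(classes, dtype=np.int64)
        probs = np.zeros((len(classes), K))
        probs[np.arange(len(classes)), classes] = 1.0
        return cls(video_id, probs, classes, fps)


@dataclass
class ExplorationSummary:
    """Per-class exploration seconds, total and per 1-minute segment."""

    video_id: str
    fps: float
    total_seconds: dict[int, Fraction]            # class -> seconds (exact)
    segment_seconds: list[dict[int, Fraction]]    # per segment
    class_names: tuple[str, ...] = ()

    def seconds(self, class_index: int) -> float:
        return float(self.total_seconds.get(class_index, Fraction(0)))

    @property
    def n_segments(self) -> int:
        return len(self.segment_seconds)

    @property
    def duration_s(self) -> float:
        return float(sum(self.total_seconds.values(), Fraction(0)))


def track_to_times(track: PredictionTrack,
                   scheme: ClassScheme | None = None) -> ExplorationSummary:
    """Total and per-segment exploration seconds from hard classes."""
    per_segment = segment_scores(track)
    K = track.K
    totals = {c: Fraction(0) for c in range(K)}
    for seg in per_segment:
        for c, s in seg.items():
            totals[c] += s
    return ExplorationSummary(
        video_id=track.video_id,
        fps=track.fps,
        total_seconds=totals,
        segment_seconds=per_segment,
        class_names=scheme.names if scheme else (),
    )


def segment_scores(track: PredictionTrack,
                   segment_s: int = SEGMENT_SECONDS) -> list[dict[int, Fraction]]:
    """Per-class seconds for each segment; the last may be shorter.

    Seconds are exact rationals (#frames / fps) so that segment sums
    equal totals and totals sum to the video duration exactly.
    """
    fps = Fraction(track.fps).limit_denominator(10**6)
    frames_per_segment = segment_s * fps  # may be fractional for odd rates
    n = len(track)
    n_segments = max(1, math.ceil(Fraction(n) / frames_per_segment)) if n else 0
    out: list[dict[int, Fraction]] = []
    for s in range(n_segments):
        a = math.ceil(s * frames_per_segment)
        b = min(n, math.ceil((s + 1) * frames_per_segment))
        counts = np.bincount(track.hard_classes[a:b], minlength=track.K)
        out.append({c: Fraction(int(counts[c])) / fps for c in range(track.K)})
    return out


@dataclass(frozen=True)
class DiscriminationIndex:
    phase: str  # 'acq' | 'test'
    value: float  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ConsistencyError("DI must lie in [0, 100]")


def discrimination_index(
    summary_or_times, phase: str,
    familiar_class: int | None = None, novel_class: int | None = None,
) -> DiscriminationIndex:
    """Compute the DI for a session.

    Accepts either an :class:`ExplorationSummary` plus the class indices
    playing the familiar/novel roles (role assignment is configuration,
    never inferred), or a plain ``(t_first, t_second)`` pair in seconds.

    For ``phase='acq'`` the two times are t_o1 and t_o1' (identical
    objects); the DI is the share of the second. For ``phase='test'``
    they are t_o1 (familiar) and t_o2 (novel); the DI is the share of
    the familiar object.
    """
    if phase not in ("acq", "test"):
        raise ConsistencyError(f"phase must be 'acq' or 'test', got {phase!r}")
    if isinstance(summary_or_times, ExplorationSummary):
        if familiar_class is None or novel_class is None:
            raise ConsistencyError("familiar_class and novel_class are required")
        t1 = summary_or_times.seconds(familiar_class)
        t2 = summary_or_times.seconds(novel_class)
    else:
        t1, t2 = (float(v) for v in summary_or_times)
    denom = t1 + t2
    if denom <= 0:
        raise UndefinedDIError(
            "zero combined exploration time; DI undefined (animal excluded)"
        )
    share = (t2 if phase == "acq" else t1) / denom
    return DiscriminationIndex(phase, share * 100.0)


def export_results_csv(
    summaries: list[ExplorationSummary],
    dis: list[tuple[str, DiscriminationIndex]] | None = None,
    path=None,
) -> pd.DataFrame:
    """Long-format results table; written to ``path`` when given.

    Rows: one per (video, class, segment); one per (video, class) total
    (segment_index empty); one per (video, DI phase).
    """
    rows = []
    names: dict[int, str] = {}
    for summ in summaries:
        if summ.class_names:
            names = dict(enumerate(summ.class_names))
        for seg_i, seg in enumerate(summ.segment_seconds):
            for c, s in sorted(seg.items()):
                rows.append({
                    "video_id": summ.video_id, "record": "segment",
                    "class": names.get(c, str(c)), "segment_index": seg_i,
                    "seconds": float(s), "phase": "", "DI": np.nan,
                })
        for c, s in sorted(summ.total_seconds.items()):
            rows.append({
                "video_id": summ.video_id, "record": "total",
                "class": names.get(c, str(c)), "segment_index": np.nan,
                "seconds": float(s), "phase": "", "DI": np.nan,
            })
    for video_id, di in dis or []:
        rows.append({
            "video_id": video_id, "record": "di", "class": "",
            "segment_index": np.nan, "seconds": np.nan,
            "phase": di.phase, "DI": di.value,
        })
    table = pd.DataFrame(
        rows,
        columns=["video_id", "record", "class", "segment_index", "seconds", "phase", "DI"],
    )
    if path is not None:
        table.to_csv(Path(path), index=False)
    return table


def median_filter_track(track: PredictionTrack, width: int = 3) -> PredictionTrack:
    """Optional smoothing of 1–3-frame prediction flips (off by default).

    Short isolated flips are mostly borderline cases; a small odd-width
    median filter over hard classes removes them without touching longer
    bouts. Probabilities are left untouched.
    """
    if width % 2 != 1 or width < 3:
        raise ConsistencyError("median filter width must be odd and >= 3")
    from scipy.ndimage import median_filter

    smoothed = median_filter(track.hard_classes, size=width, mode="nearest")
    return PredictionTrack(track.video_id, track.probabilities, smoothed, track.fps)
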