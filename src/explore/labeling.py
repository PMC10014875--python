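"""Class schemes, per-frame label tracks, class weighting and data splits.

The labeling model is deliberately simple: every frame of a video carries
exactly one class. Index 0 is always the background class ("no object" —
typically the majority class in a real experiment). Object classes score
sniffing at a particular object; behaviour classes (e.g. "stretching",
"on object") score whole-body interactions.

Class imbalance is compensated with per-class loss weights

    w_k = N / (K * x_k),   N = sum_i x_i,

where ``x_k`` is the number of labeled samples of class ``k`` and ``K``
the number of classes. The weights satisfy ``sum_k w_k * x_k = N``
exactly (computed in rational arithmetic) whenever every class has at
least one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundsError, ConsistencyError, SchemaError

logger = logging.getLogger(__name__)

BACKGROUND = 0


@dataclass(frozen=True)
class ClassScheme:
    """Ordered behaviour classes; index 0 is the background class."""

    names: tuple[str, ...]
    kinds: tuple[str, ...]  # 'background' | 'object' | 'behaviour'
    key_bindings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise SchemaError("a scheme needs a background class and at least one more")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("class names must be unique")
        if len(self.kinds) != len(self.names):
            raise SchemaError("kinds and names must align")
        if self.kinds[0] != "background" or "background" in self.kinds[1:]:
            raise SchemaError("exactly one background class, at index 0")

    @property
    def K(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown class {name!r}; scheme has {self.names}") from None

    def object_classes(self) -> list[int]:
        return [i for i, k in enumerate(self.kinds) if k == "object"]

    def behaviour_classes(self) -> list[int]:
        return [i for i, k in enumerate(self.kinds) if k == "behaviour"]

    @classmethod
    def for_objects(
        cls, n_objects: int, on_object: bool = False, stretching: bool = False
    ) -> "ClassScheme":
        names = ["no object"] + [f"object {i + 1}" for i in range(n_objects)]
        kinds = ["background"] + ["object"] * n_objects
        if stretching:
            names.append("stretching")
            kinds.append("behaviour")
        if on_object:
            names.append("on object")
            kinds.append("behaviour")
        return cls(tuple(names), tuple(kinds))


@dataclass
class LabelTrack:
    """One class index per frame of a single video."""

    video_id: str
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if self.classes.ndim != 1:
            raise ConsistencyError("classes must be a 1-D array")
        if len(self.classes) and self.classes.min() < 0:
            raise ConsistencyError("class indices must be non-negative")

    def __len__(self) -> int:
        return len(self.classes)

    def validate_against(self, scheme: ClassScheme) -> None:
        if len(self.classes) and self.classes.max() >= scheme.K:
            raise SchemaError(
                f"track for {self.video_id} uses class index {self.classes.max()} "
                f">= K={scheme.K}"
            )


# ---------------------------------------------------------------------------
# class weights


@dataclass(frozen=True)
class ClassCounts:
    counts: tuple[int, ...]  # x_k for k = 0..K-1

    def __post_init__(self) -> None:
        if not self.counts:
            raise SchemaError("empty class counts")
        if any(c < 0 for c in self.counts):
            raise SchemaError("negative class count")
        if sum(self.counts) == 0:
            raise SchemaError("at least one class must have samples")

    @property
    def N(self) -> int:
        return int(sum(self.counts))

    @property
    def K(self) -> int:
        return len(self.counts)

    @classmethod
    def from_labels(cls, classes: np.ndarray, K: int) -> "ClassCounts":
        binned = np.bincount(np.asarray(classes, dtype=np.int64), minlength=K)
        return cls(tuple(int(v) for v in binned))


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights; exact rationals with a float view."""

    exact: tuple[Fraction, ...]

    @property
    def values(self) -> np.ndarray:
        return np.array([float(w) for w in self.exact], dtype=np.float64)

    def __getitem__(self, k: int) -> float:
        return float(self.exact[k])


def compute_class_weights(counts: ClassCounts) -> ClassWeights:
    """Inverse-frequency weights ``w_k = N / (K * x_k)``.

    A class with zero samples gets weight 0 (and a logged warning) so
    that schemes may declare classes before any frame is labeled.
    """
    weights = []
    for k, x_k in enumerate(counts.counts):
        if x_k == 0:
            logger.warning("class %d has no samples; weight set to 0", k)
            weights.append(Fraction(0))
        else:
            weights.append(Fraction(counts.N, counts.K * x_k))
    return ClassWeights(tuple(weights))


# ---------------------------------------------------------------------------
# label CSV import / export

LABEL_COLUMNS_FRAMES = ("video_id", "start_frame", "end_frame", "class_name")
LABEL_COLUMNS_SECONDS = ("video_id", "start_s", "end_s", "class_name")


def _intervals_from_csv(table: pd.DataFrame, fps: float) -> pd.DataFrame:
    cols = set(table.columns)
    if {"start_frame", "end_frame"} <= cols:
        out = table[["video_id", "start_frame", "end_frame", "class_name"]].copy()
    elif {"start_s", "end_s"} <= cols:
        out = table[["video_id", "class_name"]].copy()
        out["start_frame"] = np.floor(table["start_s"] * fps).astype(int)
        out["end_frame"] = np.floor(table["end_s"] * fps).astype(int)
    else:
        raise SchemaError(
            "label CSV needs start_frame/end_frame or start_s/end_s columns"
        )
    return out


def import_labels(
    source,
    fps: float,
    frame_count: int,
    scheme: ClassScheme,
    video_id: str | None = None,
) -> LabelTrack:
    """Build a dense per-frame :class:`LabelTrack` from an interval CSV.

    Intervals are half-open in frames; the seconds dialect maps a time t
    to frame ``floor(t * fps)``. Frames outside every interval are
    background. Overlapping intervals with different classes are a
    conflict (single label per frame).
    """
    table = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if table.empty:
        vid = video_id or ""
        return LabelTrack(vid, np.zeros(frame_count, dtype=np.int64))
    table = _intervals_from_csv(table, fps)
    ids = table["video_id"].astype(str).unique()
    if video_id is None:
        if len(ids) > 1:
            raise SchemaError(f"label file covers several videos {list(ids)}; pass video_id")
        video_id = str(ids[0])
    rows = table[table["video_id"].astype(str) == video_id]

    track = np.zeros(frame_count, dtype=np.int64)
    claimed = np.full(frame_count, -1, dtype=np.int64)
    for _, row in rows.iterrows():
        cls = scheme.index_of(str(row["class_name"]))
        a, b = int(row["start_frame"]), int(row["end_frame"])
        if a < 0 or b > frame_count or a >= b:
            raise BoundsError(
                f"interval [{a},{b}) outside video of {frame_count} frames"
            )
        seg = claimed[a:b]
        conflict = (seg >= 0) & (seg != cls)
        if conflict.any():
            raise ConsistencyError(
                f"overlapping intervals with different classes near frame "
                f"{a + int(np.argmax(conflict))} of {video_id}"
            )
        claimed[a:b] = cls
        track[a:b] = cls
    return LabelTrack(video_id, track)


def export_labels(track: LabelTrack, scheme: ClassScheme, path) -> None:
    """Write non-background runs of a track as an interval CSV."""
    track.validate_against(scheme)
    rows = []
    classes = track.classes
    i = 0
    while i < len(classes):
        if classes[i] != BACKGROUND:
            j = i
            while j < len(classes) and classes[j] == classes[i]:
                j += 1
            rows.append(
                {
                    "video_id": track.video_id,
                    "start_frame": i,
                    "end_frame": j,
                    "class_name": scheme.names[classes[i]],
                }
            )
            i = j
        else:
            i += 1
    pd.DataFrame(rows, columns=list(LABEL_COLUMNS_FRAMES)).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# labeled frame sets, splitting and the correction merge


@dataclass
class LabeledFrames:
    """A sparse labeled data set: (video, frame) -> class index.

    This is what training consumes; it also supports the correction
    loop's merge, where newly labeled frames override older labels.
    """

    mapping: dict[tuple[str, int], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def refs(self) -> list[tuple[str, int]]:
        return list(self.mapping.keys())

    @property
    def classes(self) -> np.ndarray:
        return np.fromiter(self.mapping.values(), dtype=np.int64, count=len(self.mapping))

    def counts(self, K: int) -> ClassCounts:
        return ClassCounts.from_labels(self.classes, K)

    @classmethod
    def from_track(
        cls, track: LabelTrack, frames: np.ndarray | None = None
    ) -> "LabeledFrames":
        """All frames of a track (or the subset ``frames``) as labeled data."""
        idx = np.arange(len(track)) if frames is None else np.asarray(frames)
        return cls({(track.video_id, int(i)): int(track.classes[i]) for i in idx})

    @classmethod
    def from_tracks(cls, tracks, frames_per_video=None) -> "LabeledFrames":
        out = cls()
        for t in tracks:
            sub = None if frames_per_video is None else frames_per_video.get(t.video_id)
            out.mapping.update(cls.from_track(t, sub).mapping)
        return out


def merge_label_sets(old: LabeledFrames, correction: LabeledFrames) -> LabeledFrames:
    """Union of two labeled sets; on conflict the correction label wins."""
    merged = dict(old.mapping)
    merged.update(correction.mapping)
    return LabeledFrames(merged)


@dataclass
class DataSplit:
    """A stratified train/validation partition of a labeled set."""

    train_idx: np.ndarray  # positions into the labeled set's ref order
    val_idx: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.val_idx = np.asarray(self.val_idx, dtype=np.int64)
        overlap = np.intersect1d(self.train_idx, self.val_idx)
        if overlap.size:
            raise ConsistencyError("train and validation sets overlap")


def split_train_val(
    classes: np.ndarray, ratio: float = 0.8, seed: int = 0
) -> DataSplit:
    """Seeded stratified split of labeled frames into train/validation.

    Per-class train counts are apportioned by largest remainder so that
    ``|train| = round(ratio * total)`` while per-class proportions stay
    within one frame of ``ratio``. A class with fewer than 2 samples
    goes entirely to training (with a warning).
    """
    classes = np.asarray(classes, dtype=np.int64)
    total = len(classes)
    if total == 0:
        raise ConsistencyError("nothing to split")
    rng = np.random.default_rng(seed)
    target_total = int(np.floor(ratio * total + 0.5))

    uniq = np.unique(classes)
    per_class = {c: np.flatnonzero(classes == c) for c in uniq}
    quota: dict[int, int] = {}
    remainders: list[tuple[float, int]] = []
    forced = 0
    for c, idx in per_class.items():
        if len(idx) < 2:
            logger.warning("class %d has < 2 samples; kept entirely in training", c)
            quota[c] = len(idx)
            forced += len(idx)
            continue
        exact = ratio * len(idx)
        quota[c] = int(np.floor(exact))
        remainders.append((exact - quota[c], int(c)))
    # largest-remainder apportionment toward the global target
    deficit = target_total - (sum(quota.values()))
    remainders.sort(key=lambda t: (-t[0], t[1]))
    for _, c in remainders:
        if deficit <= 0:
            break
        if quota[c] < len(per_class[c]) - 1:  # keep >= 1 validation frame
            quota[c] += 1
            deficit -= 1

    train_parts, val_parts = [], []
    for c in uniq:
        idx = per_class[c].copy()
        rng.shuffle(idx)
        k = quota[int(c)]
        train_parts.append(idx[:k])
        val_parts.append(idx[k:])
    train = np.sort(np.concatenate(train_parts))
    val = np.sort(np.concatenate(val_parts))
    return DataSplit(train, val, ratio)
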