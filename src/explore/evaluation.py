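"""Evaluation against a reference rater.

Covers the metrics used to validate automated scoring: support-weighted
F1/recall/precision on frame classifications, Spearman rank correlation
between per-minute-segment scores of two raters/methods, the taxonomy
and run-length structure of misclassified frame sequences, and the
back-of-envelope model for how much scoring time the pipeline saves.

Misclassification runs matter because not all errors are equal: single
frames and very short runs (<= 3 frames) tend to be borderline cases a
human would also hesitate on, while long consecutive runs distort
exploration times and drive the correlation to the rater down. Each run
is maximal and homogeneous in its (true, predicted) pair — for a
three-class problem there are six such pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, UndefinedCorrelationError
from .labeling import LabelTrack
from .stopwatch import PredictionTrack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion matrix and weighted metrics


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ConsistencyError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ConsistencyError("negative confusion count")

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def off_diagonal_total(self) -> int:
        return self.total - int(np.trace(self.counts))


def confusion_counts(true: LabelTrack, pred: PredictionTrack,
                     K: int | None = None) -> ConfusionMatrix:
    """Tally (true, predicted) pairs over aligned frame tracks."""
    t = true.classes
    p = pred.hard_classes
    if len(t) != len(p):
        raise ConsistencyError(f"track lengths differ ({len(t)} vs {len(p)})")
    k = K or int(max(t.max(initial=0), p.max(initial=0))) + 1
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return ConfusionMatrix(cm)


def weighted_prf(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Support-weighted (F1, recall, precision) from a confusion matrix.

    Per-class precision = TP / predicted positives, recall = TP / true
    positives, F1 their harmonic mean; each is averaged over classes
    with weights proportional to true-class support. Zero denominators
    contribute 0 (logged); zero-support classes carry no weight.
    """
    counts = cm.counts
    if counts.sum() == 0:
        raise ConsistencyError("empty confusion matrix")
    tp = np.diag(counts).astype(np.float64)
    support = counts.sum(axis=1).astype(np.float64)
    predicted = counts.sum(axis=0).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    if (predicted[support > 0] == 0).any():
        logger.warning("a supported class is never predicted; precision taken as 0")
    w = support / support.sum()
    return float(w @ f1), float(w @ recall), float(w @ precision)


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman(x, y) -> float:
    """Spearman's rank correlation with average ranks for ties.

    Raises when either input is constant (ranks undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ConsistencyError("need two equal-length 1-D arrays of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input; rank correlation undefined")
    r = stats.spearmanr(x, y).statistic
    return float(r)


def segment_score_correlation(
    a: list[dict[int, object]], b: list[dict[int, object]],
    object_classes: list[int], pooled: bool = True,
):
    """Spearman r between two methods' per-segment per-object scores.

    ``a`` and ``b`` are per-segment {class: seconds} lists (one entry
    per segment, as produced by ``stopwatch.segment_scores``). With
    ``pooled`` (default) all (segment, object) scores enter one
    correlation; otherwise one r per object class is returned.
    """
    if len(a) != len(b):
        raise ConsistencyError("segment lists differ in length")
    if pooled:
        xs = [float(seg[c]) for seg in a for c in object_classes]
        ys = [float(seg[c]) for seg in b for c in object_classes]
        return spearman(xs, ys)
    return {
        c: spearman([float(seg[c]) for seg in a], [float(seg[c]) for seg in b])
        for c in object_classes
    }


# ---------------------------------------------------------------------------
# misclassification runs


@dataclass(frozen=True)
class MisclassRun:
    video_id: str
    start_frame: int
    length: int
    true_class: int
    predicted_class: int

    @property
    def pair(self) -> tuple[int, int]:
        return (self.true_class, self.predicted_class)


def misclass_runs(true: LabelTrack, pred: PredictionTrack) -> list[MisclassRun]:
    """Maximal runs of consecutive misclassified frames.

    Runs are homogeneous in (true, predicted): if either side changes
    mid-error, a new run starts. The run lengths sum to the number of
    misclassified frames exactly.
    """
    t = true.classes
    p = pred.hard_classes
    if len(t) != len(p):
        raise ConsistencyError(f"track lengths differ ({len(t)} vs {len(p)})")
    runs: list[MisclassRun] = []
    i = 0
    n = len(t)
    while i < n:
        if t[i] != p[i]:
            j = i
            while j < n and t[j] == t[i] and p[j] == p[i]:
                j += 1
            runs.append(MisclassRun(true.video_id, i, j - i, int(t[i]), int(p[i])))
            i = j
        else:
            i += 1
    return runs


def runs_by_pair(runs: list[MisclassRun]) -> dict[tuple[int, int], list[MisclassRun]]:
    out: dict[tuple[int, int], list[MisclassRun]] = {}
    for run in runs:
        out.setdefault(run.pair, []).append(run)
    return out


def run_length_accuracy_correlation(
    accuracies: np.ndarray,
    runs_per_video: list[list[MisclassRun]],
    max_length: int = 50,
    at_least: bool = False,
) -> pd.DataFrame:
    """Correlate per-video accuracy with counts of error runs per length.

    For every (true, predicted) pair and every run length L in 0..max_length,
    the count of runs of that pair with length exactly L (or >= L with
    ``at_least=True``) is computed per video and Spearman-correlated with
    the per-video accuracy scores. Cells where the counts are constant
    across videos (e.g. no such runs anywhere) are undefined and reported
    as NaN. A ``('median', r)`` row gives the median curve across pairs.
    """
    accuracies = np.asarray(accuracies, dtype=np.float64)
    n_videos = len(runs_per_video)
    if len(accuracies) != n_videos:
        raise ConsistencyError("one accuracy value per video required")
    if n_videos < 3:
        raise ConsistencyError("need at least 3 videos to correlate")
    pairs = sorted({run.pair for video in runs_per_video for run in video})
    records = []
    r_by_pair: dict[tuple[int, int], list[float]] = {p: [] for p in pairs}
    for pair in pairs:
        for L in range(max_length + 1):
            counts = np.zeros(n_videos)
            for v, video_runs in enumerate(runs_per_video):
                counts[v] = sum(
                    1 for run in video_runs
                    if run.pair == pair and (run.length >= L if at_least else run.length == L)
                )
            try:
                r = spearman(accuracies, counts)
            except UndefinedCorrelationError:
                r = np.nan
            records.append({"true": pair[0], "predicted": pair[1], "length": L, "r": r})
            r_by_pair[pair].append(r)
    table = pd.DataFrame(records)
    median_rows = []
    for L in range(max_length + 1):
        vals = [r_by_pair[p][L] for p in pairs]
        vals = [v for v in vals if not np.isnan(v)]
        median_rows.append({
            "true": -1, "predicted": -1, "length": L,
            "r": float(np.median(vals)) if vals else np.nan,
        })
    return pd.concat([table, pd.DataFrame(median_rows)], ignore_index=True)


# ---------------------------------------------------------------------------
# time saved


@dataclass(frozen=True)
class TimeSavingEstimate:
    n_videos: int
    video_min: float
    scoring_min_per_video: float
    labeled_frames: int
    fps: float
    labeled_footage_min: float
    explore_total_min: float
    manual_total_min: float
    percent_saved: float


def time_saved(
    n: int, video_min: float, scoring_min_per_video: float,
    labeled_frames: int, fps: float,
) -> TimeSavingEstimate:
    """Manual-scoring time saved by labeling only a training subset.

    Scoring effort is proportional to footage: a video of ``video_min``
    minutes takes ``scoring_min_per_video`` minutes to score, so labeling
    ``labeled_frames`` frames (``labeled_frames / (fps * 60)`` minutes of
    footage) takes that footage times the same rate. The saving is
    relative to scoring all ``n`` videos manually.
    """
    if min(n, video_min, scoring_min_per_video, labeled_frames, fps) <= 0:
        raise ConsistencyError("all inputs must be positive")
    labeled_footage_min = labeled_frames / (fps * 60.0)
    if labeled_footage_min > n * video_min:
        raise ConsistencyError("labeled footage exceeds the experiment footage")
    explore_total_min = labeled_footage_min * (scoring_min_per_video / video_min)
    manual_total_min = n * scoring_min_per_video
    percent_saved = 100.0 * (1.0 - explore_total_min / manual_total_min)
    return TimeSavingEstimate(
        n_videos=n, video_min=video_min,
        scoring_min_per_video=scoring_min_per_video,
        labeled_frames=labeled_frames, fps=fps,
        labeled_footage_min=labeled_footage_min,
        explore_total_min=explore_total_min,
        manual_total_min=manual_total_min,
        percent_saved=percent_saved,
    )
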