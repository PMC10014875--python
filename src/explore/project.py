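"""Project configuration and the staged analysis workflow.

A project is a directory with a YAML config and a fixed artifact layout:

    project/
      config.yaml
      videos/                  experiment videos (*.avi)
      sampling/  plan.json, scoring_video.avi, index_map.csv
      labels/    labeled_frames.csv (+ user-provided interval CSVs)
      model/     model.h5, history.json
      predictions/  <video>_track.csv, <video>_prediction.avi
      results/   results.csv, evaluation.json, quadrants.csv

Stages run in order: sample -> import-labels -> train -> predict ->
evaluate, with an optional correction loop (correct = merge new labels,
retrain from scratch, re-predict). Every stage logs its seed, inputs and
outputs, and fails with a :class:`WorkflowError` naming the missing
prerequisite if run out of order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, quadrant, sampling, stopwatch, synthetic, video_io
from .errors import ConfigurationError, WorkflowError
from .labeling import (
    ClassScheme, LabeledFrames, LabelTrack, compute_class_weights,
    import_labels, merge_label_sets, split_train_val,
)
from .network import FrameClassifier, NetworkSpec, load_model
from .roi import RegionOfInterest

logger = logging.getLogger(__name__)

STAGES = (
    "synth", "sample", "import-labels", "train", "predict",
    "correct", "evaluate", "quadrant",
)


@dataclass
class ProjectConfig:
    name: str
    project_dir: Path
    video_dir: Path
    fps: float = 25.0
    arena: RegionOfInterest | None = None
    object_rois: dict[int, RegionOfInterest] = field(default_factory=dict)
    class_names: tuple[str, ...] = ("no object", "object 1", "object 2")
    class_kinds: tuple[str, ...] = ("background", "object", "object")
    # sampling parameters
    n_sample_videos: int = 2
    minutes_per_video: int = 1
    scoring_minutes: int = 1
    sampling_mode: str = "random"  # random | manual
    manual_videos: tuple[str, ...] = ()
    seed: int = 0
    # training
    epochs: int | None = None
    network: dict = field(default_factory=dict)
    # analysis roles
    phase: str = "test"
    familiar_class: int = 1
    novel_class: int = 2
    # quadrant analysis
    quadrant_noise_floor: float = quadrant.DEFAULT_NOISE_FLOOR
    quadrant_min_dwell: int = quadrant.DEFAULT_MIN_DWELL

    def __post_init__(self) -> None:
        self.project_dir = Path(self.project_dir)
        self.video_dir = Path(self.video_dir)

    @property
    def scheme(self) -> ClassScheme:
        return ClassScheme(tuple(self.class_names), tuple(self.class_kinds))

    def network_spec(self) -> NetworkSpec:
        overrides = dict(self.network)
        for key in ("conv_filters", "dense_units"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return NetworkSpec(**overrides)

    # -- persistence --------------------------------------------------------

    def to_yaml(self, path=None) -> None:
        payload = {
            "name": self.name,
            "video_dir": str(self.video_dir),
            "fps": self.fps,
            "arena": self.arena.to_list() if self.arena else None,
            "object_rois": {str(k): v.to_list() for k, v in self.object_rois.items()},
            "classes": {"names": list(self.class_names), "kinds": list(self.class_kinds)},
            "sampling": {
                "n": self.n_sample_videos, "i": self.minutes_per_video,
                "j": self.scoring_minutes, "mode": self.sampling_mode,
                "manual_videos": list(self.manual_videos), "seed": self.seed,
            },
            "training": {"epochs": self.epochs, "network": self.network},
            "roles": {
                "phase": self.phase, "familiar_class": self.familiar_class,
                "novel_class": self.novel_class,
            },
            "quadrant": {
                "noise_floor": self.quadrant_noise_floor,
                "min_dwell": self.quadrant_min_dwell,
            },
        }
        target = Path(path) if path else self.project_dir / "config.yaml"
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ProjectConfig":
        path = Path(path)
        if path.is_dir():
            path = path / "config.yaml"
        if not path.exists():
            raise ConfigurationError(f"no project config at {path}")
        raw = yaml.safe_load(path.read_text())
        video_dir = Path(raw["video_dir"])
        if not video_dir.is_absolute():
            video_dir = path.parent / video_dir
        cfg = cls(
            name=raw.get("name", path.parent.name),
            project_dir=path.parent,
            video_dir=video_dir,
            fps=float(raw.get("fps", 25.0)),
            arena=RegionOfInterest.from_sequence(raw["arena"]) if raw.get("arena") else None,
            object_rois={
                int(k): RegionOfInterest.from_sequence(v)
                for k, v in (raw.get("object_rois") or {}).items()
            },
            class_names=tuple(raw["classes"]["names"]),
            class_kinds=tuple(raw["classes"]["kinds"]),
        )
        s = raw.get("sampling", {})
        cfg.n_sample_videos = int(s.get("n", cfg.n_sample_videos))
        cfg.minutes_per_video = int(s.get("i", cfg.minutes_per_video))
        cfg.scoring_minutes = int(s.get("j", cfg.scoring_minutes))
        cfg.sampling_mode = s.get("mode", cfg.sampling_mode)
        cfg.manual_videos = tuple(s.get("manual_videos", ()))
        cfg.seed = int(s.get("seed", 0))
        t = raw.get("training", {})
        cfg.epochs = t.get("epochs")
        cfg.network = t.get("network", {}) or {}
        roles = raw.get("roles", {})
        cfg.phase = roles.get("phase", cfg.phase)
        cfg.familiar_class = int(roles.get("familiar_class", cfg.familiar_class))
        cfg.novel_class = int(roles.get("novel_class", cfg.novel_class))
        q = raw.get("quadrant", {})
        cfg.quadrant_noise_floor = float(q.get("noise_floor", cfg.quadrant_noise_floor))
        cfg.quadrant_min_dwell = int(q.get("min_dwell", cfg.quadrant_min_dwell))
        return cfg


# ---------------------------------------------------------------------------
# helpers


def _video_paths(config: ProjectConfig) -> list[Path]:
    if not config.video_dir.exists():
        raise WorkflowError(f"video directory {config.video_dir} missing")
    paths = sorted(config.video_dir.glob("*.avi"))
    if not paths:
        raise WorkflowError(f"no .avi videos in {config.video_dir}")
    return paths


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise WorkflowError(
            f"missing artifact {path.name}: run the '{producing_stage}' stage first"
        )
    return path


def _preprocessed(config: ProjectConfig, stack: video_io.FrameStack) -> np.ndarray:
    return video_io.preprocess_stack(stack, config.arena)


def _log_stage(stage: str, config: ProjectConfig, seed: int, outputs: list[Path]) -> None:
    line = (
        f"stage={stage} project={config.name} seed={seed} "
        f"outputs={[str(o) for o in outputs]}"
    )
    logger.info(line)
    logfile = config.project_dir / "workflow.log"
    logfile.parent.mkdir(parents=True, exist_ok=True)
    with open(logfile, "a") as fh:
        fh.write(line + "\n")


# ---------------------------------------------------------------------------
# stages


def stage_synth(config: ProjectConfig, arena_config: synthetic.ArenaConfig,
                n_videos: int, seed: int) -> synthetic.SyntheticExperiment:
    """Generate synthetic videos plus ground-truth labels into the project."""
    exp = synthetic.generate_experiment(arena_config, n_videos, seed)
    config.video_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    truth_rows = []
    for stack, track in zip(exp.videos, exp.labels):
        path = config.video_dir / f"{stack.source_id}.avi"
        video_io.write_frames(path, stack)
        outputs.append(path)
        classes = track.classes
        i = 0
        while i < len(classes):
            if classes[i] != 0:
                j = i
                while j < len(classes) and classes[j] == classes[i]:
                    j += 1
                truth_rows.append({
                    "video_id": track.video_id, "start_frame": i,
                    "end_frame": j, "class_name": exp.scheme.names[classes[i]],
                })
                i = j
            else:
                i += 1
    truth_path = config.project_dir / "labels" / "ground_truth.csv"
    truth_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        truth_rows, columns=["video_id", "start_frame", "end_frame", "class_name"]
    ).to_csv(truth_path, index=False)
    sidecar = config.project_dir / "ground_truth.json"
    synthetic.write_ground_truth_sidecar(exp, sidecar)
    _log_stage("synth", config, seed, outputs + [truth_path, sidecar])
    return exp


def stage_sample(config: ProjectConfig) -> sampling.SamplingPlan:
    """Select representative videos and assemble the scoring video."""
    paths = _video_paths(config)
    stacks = [video_io.read_frames(p) for p in paths]
    if config.sampling_mode == "manual":
        wanted = list(config.manual_videos)
        reps = [i for i, p in enumerate(paths) if p.stem in wanted]
        if len(reps) != len(wanted):
            raise ConfigurationError(f"manual videos {wanted} not all present")
    else:
        features = np.stack([sampling.video_feature(s) for s in stacks])
        reps, _ = sampling.cluster_videos(features, config.n_sample_videos, config.seed)
    selected = [stacks[i] for i in reps]
    plan = sampling.build_scoring_plan(
        n=len(selected), i=config.minutes_per_video, j=config.scoring_minutes,
        fps=config.fps,
    )
    merged, index_map = sampling.assemble_scoring_video(plan, selected)
    out = config.project_dir / "sampling"
    out.mkdir(parents=True, exist_ok=True)
    video_io.write_frames(out / "scoring_video.avi", merged)
    index_map.to_csv(out / "index_map.csv")
    (out / "plan.json").write_text(json.dumps({
        "n": plan.n, "i": plan.i, "j": plan.j, "fps": plan.fps,
        "fraction": [plan.fraction.numerator, plan.fraction.denominator],
        "videos": [s.source_id for s in selected],
        "segments": [
            [s.video_index, s.start_frame, s.end_frame] for s in plan.segments
        ],
    }))
    _log_stage("sample", config, config.seed,
               [out / "scoring_video.avi", out / "index_map.csv", out / "plan.json"])
    return plan


def stage_import_labels(config: ProjectConfig, label_csv) -> LabeledFrames:
    """Turn an interval label CSV into the project's labeled frame set.

    Intervals on ``scoring_video`` are mapped back to source frames via
    the sampling index map; intervals on real video ids are taken as-is.
    Frames covered by the scoring video but not labeled become explicit
    background samples (the rater saw them and scored nothing).
    """
    table = pd.read_csv(label_csv)
    scheme = config.scheme
    labeled = LabeledFrames()
    ids = set(table["video_id"].astype(str)) if len(table) else set()
    if "scoring_video" in ids or not len(table):
        index_map = sampling.IndexMap.from_csv(
            _require(config.project_dir / "sampling" / "index_map.csv", "sample")
        )
        merged_len = len(index_map)
        track = import_labels(
            table[table["video_id"] == "scoring_video"] if len(table) else table,
            config.fps, merged_len, scheme, video_id="scoring_video",
        )
        for merged_idx in range(merged_len):
            vid, src = index_map.source_of(merged_idx)
            labeled.mapping[(vid, src)] = int(track.classes[merged_idx])
        ids.discard("scoring_video")
    for vid in sorted(ids):
        frame_count = int(
            table.loc[table["video_id"] == vid, "end_frame"].max()
        ) if "end_frame" in table else 0
        track = import_labels(table, config.fps, frame_count, scheme, video_id=vid)
        for idx in range(len(track)):
            labeled.mapping[(vid, idx)] = int(track.classes[idx])
    out = config.project_dir / "labels" / "labeled_frames.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    _write_labeled(labeled, out)
    _log_stage("import-labels", config, config.seed, [out])
    return labeled


def _write_labeled(labeled: LabeledFrames, path: Path) -> None:
    pd.DataFrame(
        [{"video_id": v, "frame": f, "class_index": c}
         for (v, f), c in sorted(labeled.mapping.items())]
    ).to_csv(path, index=False)


def _read_labeled(path: Path) -> LabeledFrames:
    table = pd.read_csv(path)
    return LabeledFrames({
        (str(r.video_id), int(r.frame)): int(r.class_index)
        for r in table.itertuples()
    })


def stage_train(config: ProjectConfig, seed: int | None = None):
    """Train the classifier on the labeled frames; saves model.h5."""
    seed = config.seed if seed is None else seed
    labeled = _read_labeled(
        _require(config.project_dir / "labels" / "labeled_frames.csv", "import-labels")
    )
    scheme = config.scheme
    by_video: dict[str, list[tuple[int, int]]] = {}
    for (vid, frame), cls in labeled.mapping.items():
        by_video.setdefault(vid, []).append((frame, cls))
    frames_list, y_list = [], []
    for vid in sorted(by_video):
        stack = video_io.read_frames(config.video_dir / f"{vid}.avi")
        pre = _preprocessed(config, stack)
        for frame, cls in sorted(by_video[vid]):
            frames_list.append(pre[frame])
            y_list.append(cls)
    X = np.stack(frames_list)
    y = np.asarray(y_list)
    weights = compute_class_weights(labeled.counts(scheme.K))
    split = split_train_val(y, ratio=0.8, seed=seed)
    model = FrameClassifier(X, y, scheme, class_weights=weights,
                            spec=config.network_spec())
    results = model.fit(split=split, seed=seed, epochs=config.epochs)
    out = config.project_dir / "model"
    out.mkdir(parents=True, exist_ok=True)
    results.save(out / "model.h5")
    (out / "history.json").write_text(json.dumps(results.history.as_dict()))
    _log_stage("train", config, seed, [out / "model.h5", out / "history.json"])
    return results


def stage_predict(config: ProjectConfig) -> dict[str, stopwatch.PredictionTrack]:
    """Run inference on every project video; writes tracks and results."""
    model_path = _require(config.project_dir / "model" / "model.h5", "train")
    results = load_model(model_path, scheme=config.scheme)
    pred_dir = config.project_dir / "predictions"
    pred_dir.mkdir(parents=True, exist_ok=True)
    tracks: dict[str, stopwatch.PredictionTrack] = {}
    summaries, dis = [], []
    outputs = []
    for path in _video_paths(config):
        stack = video_io.read_frames(path)
        pre = _preprocessed(config, stack)
        track = results.predict_frames(pre, fps=config.fps, video_id=path.stem)
        tracks[path.stem] = track
        table = pd.DataFrame(track.probabilities,
                             columns=[f"p_{n}" for n in config.scheme.names])
        table.insert(0, "frame", np.arange(len(track)))
        table["hard_class"] = track.hard_classes
        track_path = pred_dir / f"{path.stem}_track.csv"
        table.to_csv(track_path, index=False)
        outputs.append(track_path)
        if config.object_rois:
            video_io.render_prediction_video(
                stack, track.hard_classes, config.object_rois,
                behaviour_classes=set(config.scheme.behaviour_classes()),
                out_path=pred_dir / f"{path.stem}_prediction.avi",
            )
            outputs.append(pred_dir / f"{path.stem}_prediction.avi")
        summary = stopwatch.track_to_times(track, config.scheme)
        summaries.append(summary)
        try:
            dis.append((path.stem, stopwatch.discrimination_index(
                summary, config.phase, config.familiar_class, config.novel_class)))
        except Exception:
            logger.warning("DI undefined for %s", path.stem)
    results_dir = config.project_dir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    stopwatch.export_results_csv(summaries, dis, results_dir / "results.csv")
    outputs.append(results_dir / "results.csv")
    _log_stage("predict", config, config.seed, outputs)
    return tracks


def stage_correct(config: ProjectConfig, correction_csv, seed: int | None = None):
    """Correction loop: merge new labels, retrain from scratch, re-predict."""
    labeled_path = _require(
        config.project_dir / "labels" / "labeled_frames.csv", "import-labels"
    )
    old = _read_labeled(labeled_path)
    table = pd.read_csv(correction_csv)
    correction = LabeledFrames()
    scheme = config.scheme
    for vid in sorted(set(table["video_id"].astype(str))) if len(table) else []:
        sub = table[table["video_id"].astype(str) == vid]
        frame_count = int(sub["end_frame"].max())
        track = import_labels(sub, config.fps, frame_count, scheme, video_id=vid)
        # only frames inside corrected intervals override old labels
        for _, row in sub.iterrows():
            for idx in range(int(row["start_frame"]), int(row["end_frame"])):
                correction.mapping[(vid, idx)] = int(track.classes[idx])
    merged = merge_label_sets(old, correction)
    _write_labeled(merged, labeled_path)
    _log_stage("correct", config, config.seed, [labeled_path])
    results = stage_train(config, seed=seed)
    stage_predict(config)
    return results


def stage_evaluate(config: ProjectConfig, truth_csv=None) -> dict:
    """Compare predictions against reference labels; writes evaluation.json."""
    truth_csv = truth_csv or _require(
        config.project_dir / "labels" / "ground_truth.csv", "synth (or provide truth)"
    )
    pred_dir = _require(config.project_dir / "predictions", "predict")
    scheme = config.scheme
    truth_table = pd.read_csv(truth_csv)
    object_classes = scheme.object_classes()
    per_video = {}
    all_cm = np.zeros((scheme.K, scheme.K), dtype=np.int64)
    accuracies, runs_per_video = [], []
    for track_path in sorted(pred_dir.glob("*_track.csv")):
        vid = track_path.name[: -len("_track.csv")]
        table = pd.read_csv(track_path)
        hard = table["hard_class"].to_numpy()
        probs = table[[c for c in table.columns if c.startswith("p_")]].to_numpy()
        pred = stopwatch.PredictionTrack(vid, probs, hard, config.fps)
        truth = import_labels(truth_table, config.fps, len(hard), scheme, video_id=vid)
        cm = evaluation.confusion_counts(truth, pred, K=scheme.K)
        all_cm += cm.counts
        truth_track = stopwatch.PredictionTrack.from_hard(
            vid, truth.classes, scheme.K, config.fps
        )
        try:
            r = evaluation.segment_score_correlation(
                stopwatch.segment_scores(pred), stopwatch.segment_scores(truth_track),
                object_classes,
            )
        except Exception:
            r = float("nan")
        runs = evaluation.misclass_runs(truth, pred)
        accuracies.append(r)
        runs_per_video.append(runs)
        per_video[vid] = {
            "spearman_r": r,
            "misclassified_frames": int(cm.off_diagonal_total),
            "n_runs": len(runs),
        }
    f1, recall, precision = evaluation.weighted_prf(
        evaluation.ConfusionMatrix(all_cm)
    )
    report = {
        "weighted_f1": f1, "weighted_recall": recall, "weighted_precision": precision,
        "per_video": per_video,
        "confusion_matrix": all_cm.tolist(),
    }
    out = config.project_dir / "results" / "evaluation.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2))
    _log_stage("evaluate", config, config.seed, [out])
    return report


def stage_quadrant(config: ProjectConfig, reference_path=None) -> pd.DataFrame:
    """Quadrant occupancy and transition counts for every video."""
    rows = []
    reference = None
    if reference_path is not None:
        reference = video_io.read_frames(reference_path).frames[0].astype(np.float64).mean(axis=2)
    for path in _video_paths(config):
        stack = video_io.read_frames(path)
        track = quadrant.track_quadrants(
            stack, config.arena, reference, noise_floor=config.quadrant_noise_floor
        )
        occ = quadrant.occupancy_times(track)
        transitions = quadrant.transition_count(track, config.quadrant_min_dwell)
        row = {"video_id": path.stem, "transitions": transitions,
               "not_located_s": float(occ[quadrant.NOT_LOCATED])}
        for q in range(4):
            row[f"quadrant_{q}_s"] = float(occ[q])
        rows.append(row)
    table = pd.DataFrame(rows)
    out = config.project_dir / "results" / "quadrants.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False)
    _log_stage("quadrant", config, config.seed, [out])
    return table


def run_workflow(stage: str, config: ProjectConfig, **kwargs):
    """Dispatch a named workflow stage (see :data:`STAGES`)."""
    dispatch = {
        "sample": stage_sample,
        "import-labels": stage_import_labels,
        "train": stage_train,
        "predict": stage_predict,
        "correct": stage_correct,
        "evaluate": stage_evaluate,
        "quadrant": stage_quadrant,
    }
    if stage == "synth":
        return stage_synth(config, **kwargs)
    if stage not in dispatch:
        raise WorkflowError(f"unknown stage {stage!r}; valid stages: {STAGES}")
    return dispatch[stage](config, **kwargs)
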