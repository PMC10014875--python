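"""Synthetic top-view arena videos with exact per-frame ground truth.

The generator emulates the kind of footage an object-recognition test
produces: a static arena seen from above, one to three static circular
objects, and a single agent (a flat-shaded ellipse with a nose marker)
that roams, approaches objects, and dwells near them in exploration
bouts. Every rendered frame is driven by an explicit kinematic state, and
the per-frame class label is *derived from that same state* by the
scoring rule, so labels and pixels can never disagree.

The scoring rule mirrors manual practice in the field: a frame counts as
exploration of object k when the nose point is within a proximity
threshold of the object's boundary and the heading points into the
half-plane facing the object (a +/-90 degree cone); sitting on the object
is its own class (or excluded) depending on configuration.

Kinematics are a correlated random walk with finite-state dwell modes
(roam / approach / explore / on-object / stretch). Real recordings differ
in texture, lighting and posture variability; the generator's purpose is
a controlled, seeded test bed, not photorealism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .labeling import ClassScheme, LabelTrack
from .roi import RegionOfInterest
from .video_io import FrameStack

MODE_ROAM, MODE_APPROACH, MODE_EXPLORE, MODE_ON_OBJECT, MODE_STRETCH = range(5)
MODE_NAMES = ("roam", "approach", "explore", "on_object", "stretch")


@dataclass(frozen=True)
class ObjectSpec:
    cx: float
    cy: float
    radius: float
    intensity: float


@dataclass(frozen=True)
class AgentSpec:
    body_length_px: float = 24.0
    body_intensity: float = 60.0
    nose_offset_px: float = 12.0
    nose_intensity: float = 110.0
    nose_radius_px: float = 3.0
    max_speed_px: float = 4.0  # per frame


@dataclass(frozen=True)
class BehaviourSwitches:
    on_object: bool = False
    stretching: bool = False


@dataclass(frozen=True)
class ArenaConfig:
    """Full description of a synthetic experiment's conditions."""

    width_px: int = 200
    height_px: int = 200
    shape: str = "rectangular"  # or "circular"
    background_intensity: float = 200.0
    fps: float = 25.0
    duration_s: float = 60.0
    object_specs: tuple[ObjectSpec, ...] = (
        ObjectSpec(60.0, 60.0, 13.0, 40.0),
        ObjectSpec(140.0, 140.0, 13.0, 120.0),
    )
    agent: AgentSpec = field(default_factory=AgentSpec)
    exploration_radius_px: float = 8.0
    contrast_regime: str = "normal"  # normal | bright | dark
    behaviour_classes_enabled: BehaviourSwitches = field(default_factory=BehaviourSwitches)
    noise_sigma: float = 2.0
    low_contrast_bound: float = 20.0
    # kinematics
    attraction: bool = True
    p_approach: float = 0.3         # roam -> approach chance at mode expiry
    roam_turn_sigma: float = 0.35   # radians per frame
    explore_dwell_frames: tuple[int, int] = (10, 60)
    roam_dwell_frames: tuple[int, int] = (15, 60)
    on_object_dwell_frames: tuple[int, int] = (25, 100)
    stretch_dwell_frames: tuple[int, int] = (8, 25)
    p_on_object: float = 0.25       # explore -> on-object chance (if enabled)
    p_stretch: float = 0.2          # explore -> stretch chance (if enabled)

    def __post_init__(self) -> None:
        if self.fps < 1 or self.duration_s < 1:
            raise ConfigurationError("fps >= 1 and duration_s >= 1 required")
        if self.exploration_radius_px <= 0:
            raise ConfigurationError("exploration_radius_px must be positive")
        if self.shape not in ("rectangular", "circular"):
            raise ConfigurationError(f"unknown arena shape {self.shape!r}")
        if self.contrast_regime not in ("normal", "bright", "dark"):
            raise ConfigurationError(f"unknown contrast regime {self.contrast_regime!r}")
        for k, obj in enumerate(self.object_specs):
            if not self._disc_inside(obj.cx, obj.cy, obj.radius):
                raise ConfigurationError(f"object {k + 1} not fully inside the arena")

    # -- geometry helpers ---------------------------------------------------
    def _disc_inside(self, cx: float, cy: float, r: float) -> bool:
        if self.shape == "rectangular":
            return (
                r <= cx <= self.width_px - r and r <= cy <= self.height_px - r
            )
        ax, ay = self.width_px / 2, self.height_px / 2
        return math.hypot(cx - ax, cy - ay) + r <= min(ax, ay)

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def arena_roi(self) -> RegionOfInterest:
        return RegionOfInterest(0, 0, self.width_px, self.height_px)

    def scheme(self) -> ClassScheme:
        sw = self.behaviour_classes_enabled
        return ClassScheme.for_objects(
            len(self.object_specs), on_object=sw.on_object, stretching=sw.stretching
        )

    def object_rois(self, margin: int = 4) -> dict[int, RegionOfInterest]:
        """Class index -> bounding box around the object disc."""
        rois = {}
        for k, obj in enumerate(self.object_specs):
            r = obj.radius + margin
            rois[k + 1] = RegionOfInterest(
                max(0, int(obj.cx - r)),
                max(0, int(obj.cy - r)),
                min(self.width_px, int(math.ceil(obj.cx + r))),
                min(self.height_px, int(math.ceil(obj.cy + r))),
            )
        return rois

    @classmethod
    def for_regime(cls, regime: str, **kwargs) -> "ArenaConfig":
        """Preset intensity palettes for the three contrast regimes.

        'bright' emulates a pale animal in a pale arena, 'dark' a dark
        animal in a dark arena; in both, agent/background contrast stays
        within ``low_contrast_bound``.
        """
        presets = {
            "normal": dict(
                background_intensity=200.0,
                agent=AgentSpec(body_intensity=60.0, nose_intensity=110.0),
                object_intensities=(40.0, 120.0, 90.0),
            ),
            "bright": dict(
                background_intensity=235.0,
                agent=AgentSpec(body_intensity=225.0, nose_intensity=245.0),
                object_intensities=(215.0, 250.0, 230.0),
            ),
            "dark": dict(
                background_intensity=18.0,
                agent=AgentSpec(body_intensity=30.0, nose_intensity=8.0),
                object_intensities=(38.0, 5.0, 25.0),
            ),
        }
        p = presets[regime]
        base = cls(contrast_regime=regime, background_intensity=p["background_intensity"],
                   agent=p["agent"], **kwargs)
        objs = tuple(
            replace(o, intensity=p["object_intensities"][i % 3])
            for i, o in enumerate(base.object_specs)
        )
        return replace(base, object_specs=objs)


@dataclass
class AgentState:
    x: float
    y: float
    heading: float
    mode: int = MODE_ROAM
    mode_timer: int = 30
    target: int = 0  # object index while approaching/exploring

    def nose(self, config: ArenaConfig) -> tuple[float, float]:
        off = config.agent.nose_offset_px
        return self.x + off * math.cos(self.heading), self.y + off * math.sin(self.heading)


# ---------------------------------------------------------------------------
# scoring rule


def ground_truth_label(state: AgentState, config: ArenaConfig) -> int:
    """Class of a frame, derived from agent kinematics.

    Priority: on-object (if enabled) > stretching (if enabled) > sniffing
    at an object > background.
    """
    sw = config.behaviour_classes_enabled
    scheme = config.scheme()
    for obj in config.object_specs:
        if math.hypot(state.x - obj.cx, state.y - obj.cy) <= obj.radius:
            if sw.on_object:
                return scheme.index_of("on object")
            return 0  # being on the object is not counted
    if sw.stretching and state.mode == MODE_STRETCH:
        return scheme.index_of("stretching")
    nx, ny = state.nose(config)
    for k, obj in enumerate(config.object_specs):
        boundary_dist = math.hypot(nx - obj.cx, ny - obj.cy) - obj.radius
        if boundary_dist <= config.exploration_radius_px:
            bearing = math.atan2(obj.cy - ny, obj.cx - nx)
            if math.cos(state.heading - bearing) > 0:  # within +/-90 degrees
                return k + 1
    return 0


# ---------------------------------------------------------------------------
# kinematics


def _reflect_into_arena(config: ArenaConfig, x: float, y: float, heading: float):
    m = config.agent.body_length_px / 4  # keep the body clear of the wall
    if config.shape == "rectangular":
        if x < m:
            x, heading = 2 * m - x, math.pi - heading
        elif x > config.width_px - m:
            x, heading = 2 * (config.width_px - m) - x, math.pi - heading
        if y < m:
            y, heading = 2 * m - y, -heading
        elif y > config.height_px - m:
            y, heading = 2 * (config.height_px - m) - y, -heading
        x = min(max(x, m), config.width_px - m)
        y = min(max(y, m), config.height_px - m)
    else:
        ax, ay = config.width_px / 2, config.height_px / 2
        rmax = min(ax, ay) - m
        dx, dy = x - ax, y - ay
        d = math.hypot(dx, dy)
        if d > rmax:
            # fold back along the radius and head inward
            x = ax + dx / d * (2 * rmax - d)
            y = ay + dy / d * (2 * rmax - d)
            heading = math.atan2(ay - y, ax - x)
    return x, y, heading


def _draw_timer(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def agent_step(state: AgentState, config: ArenaConfig, rng: np.random.Generator) -> AgentState:
    """Advance the agent by one frame."""
    a = config.agent
    if a.max_speed_px == 0:  # frozen agent: only the clock advances
        new_timer = max(state.mode_timer - 1, 0)
        return AgentState(state.x, state.y, state.heading, state.mode, new_timer, state.target)
    x, y, heading, mode, timer, target = (
        state.x, state.y, state.heading, state.mode, state.mode_timer - 1, state.target
    )
    objs = config.object_specs

    if mode == MODE_ROAM:
        heading += rng.normal(0.0, config.roam_turn_sigma)
        speed = a.max_speed_px * rng.uniform(0.5, 1.0)
        x += speed * math.cos(heading)
        y += speed * math.sin(heading)
        if timer <= 0:
            if config.attraction and objs and rng.random() < config.p_approach:
                mode = MODE_APPROACH
                target = int(rng.integers(len(objs)))
                timer = 10_000  # until arrival
            else:
                timer = _draw_timer(rng, config.roam_dwell_frames)
    elif mode == MODE_APPROACH:
        obj = objs[target]
        bearing = math.atan2(obj.cy - y, obj.cx - x)
        heading += 0.4 * math.atan2(
            math.sin(bearing - heading), math.cos(bearing - heading)
        ) + rng.normal(0.0, 0.08)
        x += a.max_speed_px * math.cos(heading)
        y += a.max_speed_px * math.sin(heading)
        nx = x + a.nose_offset_px * math.cos(heading)
        ny = y + a.nose_offset_px * math.sin(heading)
        if math.hypot(nx - obj.cx, ny - obj.cy) - obj.radius <= 0.6 * config.exploration_radius_px:
            mode = MODE_EXPLORE
            timer = _draw_timer(rng, config.explore_dwell_frames)
    elif mode == MODE_EXPLORE:
        obj = objs[target]
        # hover at sniffing distance, nose locked near the object centre
        bearing = math.atan2(obj.cy - y, obj.cx - x)
        heading += 0.6 * math.atan2(
            math.sin(bearing - heading), math.cos(bearing - heading)
        ) + rng.normal(0.0, 0.12)
        hold = obj.radius + 0.3 * config.exploration_radius_px
        want_x = obj.cx - (a.nose_offset_px + hold) * math.cos(heading)
        want_y = obj.cy - (a.nose_offset_px + hold) * math.sin(heading)
        x += 0.4 * (want_x - x) + rng.normal(0.0, 0.5)
        y += 0.4 * (want_y - y) + rng.normal(0.0, 0.5)
        if timer <= 0:
            u = rng.random()
            sw = config.behaviour_classes_enabled
            if sw.on_object and u < config.p_on_object:
                mode = MODE_ON_OBJECT
                timer = _draw_timer(rng, config.on_object_dwell_frames)
            elif sw.stretching and u < config.p_on_object + config.p_stretch:
                mode = MODE_STRETCH
                timer = _draw_timer(rng, config.stretch_dwell_frames)
            else:
                mode = MODE_ROAM
                heading += math.pi * rng.uniform(0.5, 1.0)  # turn away
                timer = _draw_timer(rng, config.roam_dwell_frames)
    elif mode == MODE_ON_OBJECT:
        obj = objs[target]
        x += 0.5 * (obj.cx - x) + rng.normal(0.0, 0.4)
        y += 0.5 * (obj.cy - y) + rng.normal(0.0, 0.4)
        heading += rng.normal(0.0, 0.2)
        if timer <= 0:
            mode = MODE_ROAM
            timer = _draw_timer(rng, config.roam_dwell_frames)
    elif mode == MODE_STRETCH:
        obj = objs[target]
        bearing = math.atan2(obj.cy - y, obj.cx - x)
        heading += 0.5 * math.atan2(
            math.sin(bearing - heading), math.cos(bearing - heading)
        )
        if timer <= 0:
            mode = MODE_EXPLORE
            timer = _draw_timer(rng, config.explore_dwell_frames)

    x, y, heading = _reflect_into_arena(config, x, y, heading)
    heading = math.atan2(math.sin(heading), math.cos(heading))
    return AgentState(x, y, heading, mode, max(timer, 1) if mode != MODE_APPROACH else timer, target)


# ---------------------------------------------------------------------------
# rendering


class _Renderer:
    def __init__(self, config: ArenaConfig):
        self.config = config
        yy, xx = np.mgrid[0 : config.height_px, 0 : config.width_px]
        self.xx = xx.astype(np.float32) + 0.5
        self.yy = yy.astype(np.float32) + 0.5
        base = np.full(
            (config.height_px, config.width_px), config.background_intensity, dtype=np.float32
        )
        if config.shape == "circular":
            ax, ay = config.width_px / 2, config.height_px / 2
            outside = (self.xx - ax) ** 2 + (self.yy - ay) ** 2 > min(ax, ay) ** 2
            base[outside] = max(0.0, config.background_intensity - 60.0)
        for obj in config.object_specs:
            disc = (self.xx - obj.cx) ** 2 + (self.yy - obj.cy) ** 2 <= obj.radius**2
            base[disc] = obj.intensity
        self.base = base

    def render(self, state: AgentState, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        a = cfg.agent
        frame = self.base.copy()
        # flat-shaded ellipse body, elongated while stretching
        stretch = state.mode == MODE_STRETCH
        semi_major = a.body_length_px / 2 * (1.3 if stretch else 1.0)
        semi_minor = a.body_length_px / 4 * (0.8 if stretch else 1.0)
        ch, sh = math.cos(state.heading), math.sin(state.heading)
        dx = self.xx - state.x
        dy = self.yy - state.y
        u = dx * ch + dy * sh
        v = -dx * sh + dy * ch
        body = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
        frame[body] = a.body_intensity
        nx, ny = state.nose(cfg)
        nose = (self.xx - nx) ** 2 + (self.yy - ny) ** 2 <= a.nose_radius_px**2
        frame[nose] = a.nose_intensity
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, frame.shape).astype(np.float32)
        frame = np.clip(frame, 0, 255).astype(np.uint8)
        return np.repeat(frame[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# experiment generation


@dataclass
class SyntheticExperiment:
    """Everything a downstream stage might need, all from one seed."""

    config: ArenaConfig
    videos: list[FrameStack]
    labels: list[LabelTrack]
    trajectories: list[np.ndarray]  # per video: (N, 5) x, y, heading, mode, target
    object_rois: dict[int, RegionOfInterest]
    arena_roi: RegionOfInterest
    scheme: ClassScheme


def simulate_trajectory(
    config: ArenaConfig, rng: np.random.Generator, n_frames: int | None = None
) -> np.ndarray:
    """Simulate agent kinematics; returns (N, 5) [x, y, heading, mode, target]."""
    n = config.n_frames if n_frames is None else n_frames
    state = AgentState(
        x=config.width_px * rng.uniform(0.25, 0.75),
        y=config.height_px * rng.uniform(0.25, 0.75),
        heading=rng.uniform(-math.pi, math.pi),
        mode=MODE_ROAM,
        mode_timer=_draw_timer(rng, config.roam_dwell_frames),
    )
    out = np.empty((n, 5), dtype=np.float64)
    for i in range(n):
        out[i] = (state.x, state.y, state.heading, state.mode, state.target)
        state = agent_step(state, config, rng)
    return out


def labels_from_trajectory(
    trajectory: np.ndarray, config: ArenaConfig, video_id: str = ""
) -> LabelTrack:
    """Re-derive the per-frame label track from a stored trajectory."""
    classes = np.empty(len(trajectory), dtype=np.int64)
    for i, (x, y, heading, mode, target) in enumerate(trajectory):
        state = AgentState(x, y, heading, int(mode), 1, int(target))
        classes[i] = ground_truth_label(state, config)
    return LabelTrack(video_id, classes)


def generate_experiment(
    config: ArenaConfig, n_videos: int, seed: int
) -> SyntheticExperiment:
    """Generate ``n_videos`` seeded videos with exact ground truth.

    Identical ``(config, n_videos, seed)`` yields bit-identical pixels,
    labels and trajectories.
    """
    if n_videos < 1:
        raise ConfigurationError("n_videos must be >= 1")
    renderer = _Renderer(config)
    videos, labels, trajectories = [], [], []
    for v in range(n_videos):
        vid = f"synth{v:02d}"
        kin_rng = np.random.default_rng([seed, v, 0])
        pix_rng = np.random.default_rng([seed, v, 1])
        traj = simulate_trajectory(config, kin_rng)
        frames = np.empty(
            (len(traj), config.height_px, config.width_px, 3), dtype=np.uint8
        )
        for i, (x, y, heading, mode, target) in enumerate(traj):
            state = AgentState(x, y, heading, int(mode), 1, int(target))
            frames[i] = renderer.render(state, pix_rng)
        videos.append(FrameStack(frames, config.fps, vid))
        labels.append(labels_from_trajectory(traj, config, vid))
        trajectories.append(traj)
    return SyntheticExperiment(
        config=config,
        videos=videos,
        labels=labels,
        trajectories=trajectories,
        object_rois=config.object_rois(),
        arena_roi=config.arena_roi,
        scheme=config.scheme(),
    )


def write_ground_truth_sidecar(experiment: SyntheticExperiment, path) -> None:
    """JSON sidecar with trajectories, ROIs and the class scheme."""
    payload = {
        "fps": experiment.config.fps,
        "arena_roi": experiment.arena_roi.to_list(),
        "object_rois": {str(k): r.to_list() for k, r in experiment.object_rois.items()},
        "classes": list(experiment.scheme.names),
        "videos": [
            {
                "video_id": stack.source_id,
                "trajectory": traj.tolist(),
                "labels": track.classes.tolist(),
            }
            for stack, traj, track in zip(
                experiment.videos, experiment.trajectories, experiment.labels
            )
        ],
    }
    Path(path).write_text(json.dumps(payload))
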