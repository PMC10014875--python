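"""Generator contracts: determinism, labeling rule, kinematics, contrast."""

import math

import numpy as np
import pytest

from explore.errors import ConfigurationError
from explore.synthetic import (
    MODE_ROAM, MODE_STRETCH, AgentSpec, AgentState, ArenaConfig,
    BehaviourSwitches, ObjectSpec, agent_step, generate_experiment,
    ground_truth_label, labels_from_trajectory, simulate_trajectory,
)


class TestArenaConfig:
    def test_object_outside_arena_rejected(self):
        with pytest.raises(ConfigurationError):
            ArenaConfig(object_specs=(ObjectSpec(5.0, 5.0, 13.0, 40.0),))

    def test_object_outside_circular_arena_rejected(self):
        # corner position is inside the square but outside the circle
        with pytest.raises(ConfigurationError):
            ArenaConfig(shape="circular",
                        object_specs=(ObjectSpec(30.0, 30.0, 13.0, 40.0),))

    @pytest.mark.parametrize("kwargs", [
        {"fps": 0.5}, {"duration_s": 0.2}, {"exploration_radius_px": 0.0},
        {"shape": "hexagonal"}, {"contrast_regime": "sepia"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ArenaConfig(**kwargs)


class TestGroundTruthLabel:
    CFG = ArenaConfig()

    def test_nose_at_boundary_heading_at_centre_scores_object(self):
        obj = self.CFG.object_specs[0]  # at (60, 60), r = 13
        # nose 1 px from the boundary, heading straight at the centre
        d = obj.radius + 1.0 + self.CFG.agent.nose_offset_px
        state = AgentState(obj.cx + d, obj.cy, heading=math.pi)
        assert ground_truth_label(state, self.CFG) == 1

    def test_nose_close_but_heading_away_is_background(self):
        # nose inside the proximity ring, but the heading points out of
        # the +/-90 degree cone toward the object -> not exploration
        obj = self.CFG.object_specs[0]
        state = AgentState(obj.cx + obj.radius + 4.0, obj.cy, heading=math.pi / 2)
        nx, ny = state.nose(self.CFG)
        assert math.hypot(nx - obj.cx, ny - obj.cy) - obj.radius <= 8.0
        assert ground_truth_label(state, self.CFG) == 0

    def test_far_from_objects_is_background(self):
        state = AgentState(100.0, 20.0, heading=0.0)
        assert ground_truth_label(state, self.CFG) == 0

    def test_second_object_gets_its_own_class(self):
        obj = self.CFG.object_specs[1]
        d = obj.radius + 1.0 + self.CFG.agent.nose_offset_px
        state = AgentState(obj.cx - d, obj.cy, heading=0.0)
        assert ground_truth_label(state, self.CFG) == 2

    def test_on_object_toggle(self):
        obj = self.CFG.object_specs[0]
        state = AgentState(obj.cx, obj.cy, heading=0.0)
        assert ground_truth_label(state, self.CFG) == 0  # excluded by default
        cfg_on = ArenaConfig(
            behaviour_classes_enabled=BehaviourSwitches(on_object=True)
        )
        label = ground_truth_label(state, cfg_on)
        assert cfg_on.scheme().names[label] == "on object"

    def test_stretch_mode_labels_stretching_when_enabled(self):
        cfg = ArenaConfig(
            behaviour_classes_enabled=BehaviourSwitches(stretching=True)
        )
        state = AgentState(100.0, 20.0, heading=0.0, mode=MODE_STRETCH)
        assert cfg.scheme().names[ground_truth_label(state, cfg)] == "stretching"


class TestAgentStep:
    def test_zero_speed_only_advances_clock(self):
        cfg = ArenaConfig(agent=AgentSpec(max_speed_px=0.0))
        state = AgentState(100.0, 100.0, 0.3, MODE_ROAM, mode_timer=10)
        rng = np.random.default_rng(0)
        nxt = agent_step(state, cfg, rng)
        assert (nxt.x, nxt.y, nxt.heading, nxt.mode) == (100.0, 100.0, 0.3, MODE_ROAM)
        assert nxt.mode_timer == 9

    @pytest.mark.parametrize("shape", ["rectangular", "circular"])
    def test_positions_stay_inside_arena(self, shape):
        cfg = ArenaConfig(shape=shape, object_specs=(ObjectSpec(100.0, 100.0, 13.0, 40.0),))
        traj = simulate_trajectory(cfg, np.random.default_rng(5), n_frames=10_000)
        x, y = traj[:, 0], traj[:, 1]
        assert (x >= 0).all() and (x <= cfg.width_px).all()
        assert (y >= 0).all() and (y <= cfg.height_px).all()
        if shape == "circular":
            r = np.hypot(x - 100, y - 100)
            assert (r <= 100.0 + 1e-9).all()

    def test_attraction_concentrates_time_near_objects(self):
        """With object attraction, occupancy near objects must clearly
        exceed the area-proportional expectation of a uniform walker."""
        cfg = ArenaConfig()
        traj = simulate_trajectory(cfg, np.random.default_rng(9), n_frames=8_000)
        near = np.zeros(len(traj), dtype=bool)
        radius = 30.0  # covers the hover distance of an exploring agent
        for obj in cfg.object_specs:
            near |= np.hypot(traj[:, 0] - obj.cx, traj[:, 1] - obj.cy) < radius
        area_fraction = 2 * math.pi * radius**2 / (cfg.width_px * cfg.height_px)
        assert near.mean() > 1.5 * area_fraction


class TestGenerateExperiment:
    def test_identical_seed_bit_identical(self):
        cfg = ArenaConfig(duration_s=4.0, fps=5.0)
        a = generate_experiment(cfg, 2, seed=42)
        b = generate_experiment(cfg, 2, seed=42)
        for va, vb in zip(a.videos, b.videos):
            np.testing.assert_array_equal(va.frames, vb.frames)
        for la, lb in zip(a.labels, b.labels):
            np.testing.assert_array_equal(la.classes, lb.classes)

    def test_frame_count_and_label_length(self):
        cfg = ArenaConfig(duration_s=3.0, fps=7.0)
        exp = generate_experiment(cfg, 1, seed=0)
        assert len(exp.videos[0]) == 21
        assert len(exp.labels[0]) == 21

    def test_labels_rederivable_from_trajectory(self, short_experiment):
        exp = short_experiment
        rederived = labels_from_trajectory(
            exp.trajectories[0], exp.config, exp.labels[0].video_id
        )
        np.testing.assert_array_equal(rederived.classes, exp.labels[0].classes)

    def test_attraction_disabled_yields_all_background(self):
        cfg = ArenaConfig(duration_s=20.0, fps=5.0, attraction=False)
        exp = generate_experiment(cfg, 1, seed=2)
        # the roaming walker may still brush an object by chance, but with
        # attraction off no approach/explore bout ever starts
        assert (exp.trajectories[0][:, 3] == MODE_ROAM).all()

    def test_default_exploration_fraction_band(self):
        """Frozen after a pilot of the default conditions: a 60 s session
        spends a plausible minority of frames exploring."""
        exp = generate_experiment(ArenaConfig(), 1, seed=7)
        fraction = float((exp.labels[0].classes != 0).mean())
        assert 0.05 <= fraction <= 0.40

    @pytest.mark.parametrize("regime,low", [("normal", False), ("bright", True), ("dark", True)])
    def test_contrast_regimes(self, regime, low):
        cfg = ArenaConfig.for_regime(regime, duration_s=2.0, fps=5.0)
        gap = abs(cfg.agent.body_intensity - cfg.background_intensity)
        if low:
            assert gap <= cfg.low_contrast_bound
        else:
            assert gap > cfg.low_contrast_bound
        # and the rendered pixels actually follow the palette
        exp = generate_experiment(cfg, 1, seed=1)
        frame = exp.videos[0].frames[0].astype(float)
        corner = frame[:10, :10].mean()
        assert abs(corner - cfg.background_intensity) < 5.0

    def test_invalid_n_videos(self):
        with pytest.raises(ConfigurationError):
            generate_experiment(ArenaConfig(), 0, seed=1)
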