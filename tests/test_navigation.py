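"""Sensing, reward bookkeeping, environment mechanics and evaluation."""

import math

import numpy as np
import pytest

from swimchemo.chem_fields import get_field, make_linear_radial
from swimchemo.gait_control import OracleGaitController
from swimchemo.hydrodynamics import Actuation, SwimmerState
from swimchemo.navigation import (
    NavConfig,
    NavEnv,
    PointNavEnv,
    compute_reward,
    evaluate_policy,
    greedy_source_stub,
    sense,
    write_aggregate_json,
    write_trials_csv,
)


class ZeroMotionController:
    """Controller stub that never actuates."""

    def reset(self):
        pass

    def __call__(self, state, theta_T):
        return Actuation()


class TestSense:
    def test_centroid_sensor_reads_field_at_centroid(self):
        field = get_field("training")
        st = SwimmerState.from_centroid([3.0, 4.0], 0.7)
        c = sense(field, st, 0.0)
        rc = st.r_c
        assert c == pytest.approx(float(field(rc[0], rc[1])))

    def test_swimmer_at_source_reads_one(self):
        field = get_field("training")
        st = SwimmerState.from_centroid([0.0, 0.0], 0.0)
        assert sense(field, st, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_offset_sensor_rotates_with_the_body(self):
        field = make_linear_radial((0.0, 0.0))
        cfg = NavConfig(sensor_offset=(0.5, 0.0))
        st = SwimmerState.from_centroid([2.0, 0.0], math.pi / 2)
        # body x-axis points along +y: sensor sits at r_c + (0, 0.5)
        expected = float(field(2.0, 0.5))
        assert sense(field, st, 0.0, cfg) == pytest.approx(expected, abs=1e-12)


class TestComputeReward:
    @pytest.mark.parametrize(
        "dC,dr,expected",
        [
            (0.02, (0.05, 0.0), 0.1),
            (0.0, (5.0, 5.0), 0.0),
            (-0.02, (0.0, 0.05), -0.1),
        ],
    )
    def test_printed_formula(self, dC, dr, expected):
        assert compute_reward(dC, np.array(dr), alpha=100.0) == pytest.approx(expected)


class TestNavEnv:
    def test_zero_motion_gives_zero_deltas_and_reward(self):
        env = NavEnv(get_field("training"), ZeroMotionController(), seed=0)
        env.reset()
        obs, r, done, info = env.step(0.3)
        assert r == 0.0
        assert np.allclose(info["delta_rc"], 0.0)
        assert info["delta_C"] == 0.0
        assert not done

    def test_first_observation_is_all_deltas_zero(self):
        env = NavEnv(get_field("training"), ZeroMotionController(), seed=1)
        obs = env.reset()
        assert obs[0] == 0.0 and obs[1] == 0.0 and obs[2] == 0.0
        # with the raw (world-frame) encoding the orientation appears as a
        # unit vector in the last two slots
        cfg = NavConfig(body_frame=False)
        env2 = NavEnv(get_field("training"), ZeroMotionController(), cfg, seed=1)
        obs2 = env2.reset()
        assert obs2[3] ** 2 + obs2[4] ** 2 == pytest.approx(1.0, abs=1e-6)

    def test_time_advances_by_sensing_interval(self):
        cfg = NavConfig()
        env = NavEnv(get_field("training"), ZeroMotionController(), cfg, seed=2)
        env.reset()
        _, _, _, info = env.step(0.0)
        assert info["t"] == pytest.approx(cfg.sensing_interval * cfg.inner_dt)

    def test_reward_matches_recomputation_from_trajectory(self):
        # bookkeeping: sum of rewards equals sum of dC * alpha * |dr|
        # recomputed from the sensed series
        field = get_field("training")
        env = NavEnv(field, OracleGaitController(), NavConfig(init_annulus=(4, 6)),
                     seed=3)
        obs = env.reset()
        total = 0.0
        recomputed = 0.0
        C_prev = env._C
        rc_prev = env.state.r_c.copy()
        for k in range(40):
            theta = greedy_source_stub(obs, env)
            obs, r, done, info = env.step(theta)
            total += r
            C_now = info["C"]
            rc_now = env.state.r_c.copy()
            recomputed += (C_now - C_prev) * 100.0 * np.linalg.norm(rc_now - rc_prev)
            C_prev, rc_prev = C_now, rc_now
            if done:
                break
        assert total == pytest.approx(recomputed, abs=1e-9)

    def test_done_when_entering_reach_radius(self):
        cfg = NavConfig(init_annulus=(1.2, 1.2), reach_radius=1.0)
        env = NavEnv(get_field("training"), OracleGaitController(), cfg, seed=5)
        obs = env.reset()
        done = False
        k = 0
        while not done and k < 400:
            theta = greedy_source_stub(obs, env)
            obs, _, done, info = env.step(theta)
            k += 1
        assert done and info["reached"]
        # reach time recorded at the first inner step inside the disc
        assert info["reach_time"] <= info["t"]
        d = np.linalg.norm(env.state.r_c - env.field.source(env.t))
        assert d < cfg.reach_radius + 0.06  # at most one stroke of overshoot

    def test_timeout_censors_episode(self):
        cfg = NavConfig(t_max=10.0)
        env = NavEnv(get_field("training"), ZeroMotionController(), cfg, seed=6)
        env.reset()
        done = False
        n = 0
        while not done:
            _, _, done, info = env.step(0.0)
            n += 1
        assert n == 2  # 2 sensing events of 5 time units each
        assert info["timeout"] and not info["reached"]

    def test_mapbased_observation_is_absolute_and_field_free(self):
        env = NavEnv(get_field("training"), ZeroMotionController(), seed=7,
                     observation="mapbased")
        obs = env.reset()
        assert obs.shape == (4,)
        rc = env.state.r_c
        assert obs[0] == pytest.approx(rc[0], abs=1e-5)
        assert obs[1] == pytest.approx(rc[1], abs=1e-5)

    def test_annulus_and_preset_initial_conditions(self):
        cfg = NavConfig(init_annulus=(8.0, 15.0))
        env = NavEnv(get_field("training"), ZeroMotionController(), cfg, seed=8)
        for _ in range(20):
            env.reset()
            r = np.linalg.norm(env.state.r_c)
            assert 8.0 <= r <= 15.0
            assert env.state.L1 == 1.0 and env.state.L2 == 1.0
            assert env.state.thetaA == pytest.approx(math.pi)
        env2 = NavEnv(get_field("training"), ZeroMotionController(), cfg, seed=9,
                      init_preset=([-3.0, 0.0], 0.0))
        env2.reset()
        assert np.allclose(env2.state.r_c, [-3.0, 0.0], atol=1e-12)
        assert env2.state.theta_c == pytest.approx(0.0, abs=1e-12)


class TestPointNavEnv:
    def test_straight_up_gradient_reward_arithmetic(self):
        # moving distance d straight up the training gradient: dC = d/20,
        # reward = 100 * (d/20) * d = 5 d^2
        field = get_field("training")
        cfg = NavConfig(init_annulus=(10.0, 10.0))
        env = PointNavEnv(field, cfg, seed=0, step_size=1.0)
        env.reset()
        # aim exactly at the source
        d = env.field.source(0.0) - env.pos
        theta = math.atan2(d[1], d[0])
        _, r, _, info = env.step(theta)
        assert info["delta_C"] == pytest.approx(1.0 / 20.0, abs=1e-12)
        assert r == pytest.approx(5.0, abs=1e-9)

    def test_greedy_stub_reaches_source(self):
        res = evaluate_policy(greedy_source_stub, get_field("training"), 20,
                              NavConfig(), seed=1, env_cls=PointNavEnv)
        assert res.success_rate == 1.0
        assert res.mean_t_reach < 200.0


class TestEvaluatePolicy:
    def test_never_moving_policy_fails_all_trials_censored(self):
        cfg = NavConfig(t_max=20.0)
        res = evaluate_policy(
            lambda obs, env: 0.0, get_field("training"), 5, cfg, seed=2,
            controller_factory=ZeroMotionController,
        )
        assert res.success_rate == 0.0
        assert res.t_reach == [20.0] * 5

    def test_greedy_stub_hits_every_trial(self):
        cfg = NavConfig(init_annulus=(3.0, 5.0))
        res = evaluate_policy(
            greedy_source_stub, get_field("training"), 5, cfg, seed=3,
            controller_factory=OracleGaitController,
        )
        assert res.success_rate == 1.0
        assert all(t < cfg.t_max for t in res.t_reach)

    def test_same_seed_identical_results(self):
        cfg = NavConfig(init_annulus=(3.0, 4.0))
        kw = dict(nav_config=cfg, seed=4, controller_factory=OracleGaitController)
        r1 = evaluate_policy(greedy_source_stub, get_field("training"), 4, **kw)
        r2 = evaluate_policy(greedy_source_stub, get_field("training"), 4, **kw)
        assert r1.success == r2.success
        assert r1.t_reach == r2.t_reach

    def test_censored_sem_convention_and_writers(self, tmp_path):
        cfg = NavConfig(t_max=20.0)
        res = evaluate_policy(
            lambda obs, env: 0.0, get_field("training"), 4, cfg, seed=5,
            controller_factory=ZeroMotionController,
        )
        assert res.mean_t_reach == 20.0
        assert res.sem_t_reach == 0.0
        write_trials_csv(tmp_path / "trials.csv", res, seed=5)
        write_aggregate_json(tmp_path / "agg.json", res, cfg)
        import json

        with open(tmp_path / "agg.json") as fh:
            agg = json.load(fh)
        assert agg["success_rate"] == 0.0
        assert "t_max" in agg["censoring"]
        lines = (tmp_path / "trials.csv").read_text().strip().splitlines()
        assert len(lines) == 5  # header + 4 trials
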