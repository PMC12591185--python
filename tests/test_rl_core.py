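"""The two learners: surrogate objective, targets, buffers, reproducibility."""

import math

import numpy as np
import pytest

from swimchemo.nn import MLP, Adam
from swimchemo.rl_core import (
    PPOAgent,
    PPOConfig,
    ReplayBuffer,
    SACAgent,
    SACConfig,
    action_to_angle,
    clipped_surrogate,
    compute_gae,
    load_checkpoint,
    polyak_update,
)


class TestMLP:
    def test_hidden_layout_is_fixed(self):
        with pytest.raises(ValueError):
            MLP(4, 2, hidden=(64, 64))
        net = MLP(4, 2)
        assert [w.shape for w in net.W] == [(4, 128), (128, 128), (128, 2)]

    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = MLP(3, 2, rng=rng)
        x = rng.standard_normal((4, 3)).astype(np.float32)
        dout = rng.standard_normal((4, 2)).astype(np.float32)
        _, cache = net.forward(x, need_cache=True)
        grads, dx = net.backward(dout, cache)
        # check a weight gradient and the input gradient numerically
        eps = 1e-3
        w = net.W[0]
        i, j = 1, 5
        w[i, j] += eps
        up = float((net.forward(x) * dout).sum())
        w[i, j] -= 2 * eps
        dn = float((net.forward(x) * dout).sum())
        w[i, j] += eps
        assert grads[0][i, j] == pytest.approx((up - dn) / (2 * eps), rel=2e-2, abs=1e-3)
        x2 = x.copy()
        x2[2, 1] += eps
        up = float((net.forward(x2) * dout).sum())
        x2[2, 1] -= 2 * eps
        dn = float((net.forward(x2) * dout).sum())
        assert dx[2, 1] == pytest.approx((up - dn) / (2 * eps), rel=2e-2, abs=1e-3)


class TestPolyak:
    def test_tau_one_copies_online(self):
        online = [np.full((2, 2), 3.0)]
        target = [np.zeros((2, 2))]
        polyak_update(online, target, 1.0)
        assert np.allclose(target[0], 3.0)

    def test_half_mix(self):
        online, target = [np.array([2.0])], [np.array([0.0])]
        polyak_update(online, target, 0.5)
        assert target[0][0] == pytest.approx(1.0)

    def test_geometric_convergence(self):
        online, target = [np.array([1.0])], [np.array([0.0])]
        for _ in range(200):
            polyak_update(online, target, 0.05)
        assert target[0][0] == pytest.approx(1.0, abs=1e-4)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            polyak_update([np.zeros(2)], [np.zeros(3)], 0.5)


class TestClippedSurrogate:
    @pytest.mark.parametrize(
        "ratio,adv,expected",
        [
            (1.5, 1.0, 1.2),   # clipped from above
            (1.0, 2.0, 2.0),   # identity at the old policy
            (0.5, -1.0, -0.8), # pessimistic branch for negative advantage
            (1.5, -1.0, -1.5),
            (1.0, 0.0, 0.0),
        ],
    )
    def test_values(self, ratio, adv, expected):
        assert clipped_surrogate(ratio, adv, 0.2) == pytest.approx(expected)

    def test_equals_unclipped_at_ratio_one(self):
        adv = np.linspace(-2, 2, 9)
        assert np.allclose(clipped_surrogate(np.ones(9), adv, 0.2), adv)


class TestReplayBuffer:
    def test_fifo_eviction_at_capacity(self):
        buf = ReplayBuffer(5, 1, 1, seed=0)
        for i in range(8):
            buf.add([i], [0], 0.0, [0], False)
        assert len(buf) == 5
        assert set(buf.obs[:, 0]) == {3, 4, 5, 6, 7}

    def test_seeded_sampling_is_reproducible(self):
        def batch(seed):
            buf = ReplayBuffer(100, 1, 1, seed=seed)
            for i in range(50):
                buf.add([i], [0], float(i), [0], False)
            return buf.sample(16)[0]

        assert np.array_equal(batch(9), batch(9))
        assert not np.array_equal(batch(9), batch(10))


class TestGAE:
    def test_discount_free_limit_matches_rewards_minus_values(self):
        r = np.array([1.0, 2.0, 3.0])
        v = np.array([0.5, 0.5, 0.5])
        adv, ret = compute_gae(r, v, np.zeros(3), 0.0, gamma=0.0, lam=0.95)
        assert np.allclose(adv, r - v)
        assert np.allclose(ret, r)

    def test_terminal_cuts_bootstrap(self):
        r = np.array([0.0, 1.0])
        v = np.array([0.0, 0.0])
        adv, _ = compute_gae(r, v, np.array([0.0, 1.0]), last_value=100.0,
                             gamma=0.9, lam=1.0)
        assert adv[1] == pytest.approx(1.0)  # done=True ignores last_value


class TestSACAgent:
    def test_select_action_bounds_and_angle_range(self):
        ag = SACAgent(3, 2, SACConfig(seed=4))
        for _ in range(50):
            a = ag.select_action(np.zeros(3))
            assert np.all(np.abs(a) <= 1.0)
            th = action_to_angle(a)
            assert -math.pi < th <= math.pi

    def test_deterministic_mode_is_repeatable(self):
        ag = SACAgent(3, 2, SACConfig(seed=4))
        obs = np.array([0.3, -0.2, 1.0])
        assert np.array_equal(ag.select_action(obs, deterministic=True),
                              ag.select_action(obs, deterministic=True))

    def test_gamma_zero_target_is_reward_only_on_q(self):
        # with gamma = 0 and squared loss, repeated updates regress both
        # critics onto the immediate reward
        cfg = SACConfig(gamma=1e-12, batch_size=16, seed=0, buffer_capacity=100,
                        lr=3e-3, normalize_obs=False)
        ag = SACAgent(2, 2, cfg)
        rng = np.random.default_rng(0)
        for _ in range(64):
            ag.observe(rng.normal(size=2), rng.uniform(-1, 1, 2), 1.5,
                       rng.normal(size=2), False)
        for _ in range(800):
            ag.update()
        sa = np.concatenate([ag.buffer.obs[:64], ag.buffer.act[:64]], axis=1)
        q = ag.q1.forward(sa)[:, 0]
        assert np.mean(q) == pytest.approx(1.5, abs=0.2)

    def test_done_excludes_bootstrap(self):
        cfg = SACConfig(gamma=0.99, batch_size=8, seed=1, buffer_capacity=50,
                        lr=3e-3, normalize_obs=False)
        ag = SACAgent(1, 1, cfg)
        # all transitions terminal with reward 2: Q must approach 2, not 2/(1-gamma)
        rng = np.random.default_rng(1)
        for _ in range(32):
            ag.observe([0.0], rng.uniform(-1, 1, 1), 2.0, [0.0], True)
        for _ in range(600):
            ag.update()
        q = ag.q1.forward(np.array([0.0, 0.0], np.float32))
        assert q[0] == pytest.approx(2.0, abs=0.3)

    def test_seeded_updates_are_bitwise_reproducible(self):
        def run(seed):
            ag = SACAgent(3, 2, SACConfig(seed=seed, batch_size=16,
                                          buffer_capacity=100))
            rng = np.random.default_rng(99)
            for _ in range(40):
                ag.observe(rng.normal(size=3), rng.uniform(-1, 1, 2),
                           rng.normal(), rng.normal(size=3), False)
            for _ in range(20):
                ag.update()
            return ag.actor.W[0].copy()

        assert np.array_equal(run(5), run(5))
        assert not np.array_equal(run(5), run(6))

    def test_checkpoint_roundtrip_is_bitwise(self, tmp_path):
        ag = SACAgent(3, 2, SACConfig(seed=2, batch_size=8, buffer_capacity=64))
        rng = np.random.default_rng(0)
        for _ in range(32):
            ag.observe(rng.normal(size=3), rng.uniform(-1, 1, 2),
                       rng.normal(), rng.normal(size=3), False)
        for _ in range(10):
            ag.update()
        path = tmp_path / "sac.npz"
        ag.save(path, extra_meta={"note": "test"})
        ag2 = SACAgent.load(path)
        for p, q in zip(ag.actor.parameters(), ag2.actor.parameters()):
            assert np.array_equal(p, q)
        for p, q in zip(ag.q1_targ.parameters(), ag2.q1_targ.parameters()):
            assert np.array_equal(p, q)
        obs = np.array([0.1, 0.2, 0.3])
        assert np.array_equal(ag.select_action(obs, deterministic=True),
                              ag2.select_action(obs, deterministic=True))
        # stochastic actions continue the same RNG stream
        assert np.array_equal(ag.select_action(obs), ag2.select_action(obs))
        _, meta = load_checkpoint(path)
        assert meta["note"] == "test"
        assert meta["config_hash"]


class TestPPOAgent:
    def test_zero_advantage_means_zero_actor_gradient(self):
        cfg = PPOConfig(seed=0, epochs=1, minibatch_size=8, normalize_obs=False,
                        ent_coef=0.0)
        ag = PPOAgent(2, 1, cfg)
        before = [w.copy() for w in ag.actor.parameters()]
        rng = np.random.default_rng(0)
        obs = rng.normal(size=(8, 2)).astype(np.float32)
        acts, logps = [], []
        for o in obs:
            a, lp, _ = ag.act(o)
            acts.append(a)
            logps.append(lp)
        # advantages identically zero after normalization stay zero
        ag.update(obs, np.array(acts), np.array(logps), np.zeros(8), np.zeros(8))
        for b, a in zip(before, ag.actor.parameters()):
            assert np.array_equal(b, a)

    def test_solves_target_alignment_toy(self):
        # 1D steering task: state is the heading error (cos, sin), the
        # action turns by up to pi rad (enough to null any error in one
        # step), reward is cos(error); solved means the greedy policy holds
        # mean reward above 0.95
        cfg = PPOConfig(seed=3, rollout_steps=512, epochs=8, minibatch_size=128,
                        gamma=0.9, normalize_obs=False)
        ag = PPOAgent(2, 1, cfg)
        rng = np.random.default_rng(12)

        def episode(policy_det=False, steps=16):
            err = rng.uniform(-math.pi, math.pi)
            obs_list, act_list, logp_list, rew_list, done_list, val_list = [], [], [], [], [], []
            total = 0.0
            for k in range(steps):
                o = np.array([math.cos(err), math.sin(err)], np.float32)
                a, lp, v = ag.act(o, deterministic=policy_det)
                err = math.remainder(err - math.pi * math.tanh(float(a[0])), 2 * math.pi)
                r = math.cos(err)
                total += r
                obs_list.append(o); act_list.append(a); logp_list.append(lp)
                rew_list.append(r); done_list.append(k == steps - 1); val_list.append(v)
            return obs_list, act_list, logp_list, rew_list, done_list, val_list, total / steps

        for update in range(80):
            O, A, LP, R, D, V = [], [], [], [], [], []
            while len(O) < cfg.rollout_steps:
                o, a, lp, r, d, v, _ = episode()
                O += o; A += a; LP += lp; R += r; D += d; V += v
            adv, ret = compute_gae(np.array(R), np.array(V), np.array(D, float),
                                   0.0, cfg.gamma, cfg.lam)
            ag.update(np.array(O), np.array(A), np.array(LP), adv, ret)
        mean_r = np.mean([episode(policy_det=True)[-1] for _ in range(20)])
        assert mean_r > 0.95

    def test_checkpoint_roundtrip(self, tmp_path):
        ag = PPOAgent(4, 3, PPOConfig(seed=1))
        path = tmp_path / "ppo.npz"
        ag.save(path)
        ag2 = PPOAgent.load(path)
        obs = np.arange(4, dtype=np.float32)
        a1, _, v1 = ag.act(obs, deterministic=True)
        a2, _, v2 = ag2.act(obs, deterministic=True)
        assert np.array_equal(a1, a2)
        assert v1 == v2
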