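"""From-scratch deep reinforcement learning: PPO and SAC.

Two learners are implemented directly on top of :mod:`swimchemo.nn`:

* an on-policy clipped-surrogate policy gradient (PPO) with generalized
  advantage estimation, used for the locomotory-gait predictor;
* an off-policy entropy-regularized actor-critic (SAC) with the clipped
  double-Q trick, two polyak-averaged target Q-networks and automatic
  entropy-coefficient tuning, used for the chemotactic navigator.

All stochasticity flows through per-agent ``numpy.random.Generator``
instances, so seeded training runs are bitwise reproducible on one machine.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .nn import MLP, Adam

__all__ = [
    "Transition",
    "ReplayBuffer",
    "RunningNorm",
    "SACConfig",
    "PPOConfig",
    "polyak_update",
    "clipped_surrogate",
    "action_to_angle",
    "SACAgent",
    "PPOAgent",
    "compute_gae",
    "save_checkpoint",
    "load_checkpoint",
]

LOG_STD_MIN, LOG_STD_MAX = -5.0, 2.0


@dataclass
class Transition:
    """One environment interaction (s, a, r, s', done)."""

    state: np.ndarray
    action: np.ndarray
    reward: float
    next_state: np.ndarray
    done: bool


class ReplayBuffer:
    """Fixed-capacity FIFO buffer with seeded uniform minibatch sampling."""

    def __init__(self, capacity: int, obs_dim: int, act_dim: int, seed: int = 0):
        self.capacity = int(capacity)
        self.obs = np.zeros((capacity, obs_dim), dtype=np.float32)
        self.act = np.zeros((capacity, act_dim), dtype=np.float32)
        self.rew = np.zeros(capacity, dtype=np.float32)
        self.nobs = np.zeros((capacity, obs_dim), dtype=np.float32)
        self.done = np.zeros(capacity, dtype=np.float32)
        self.ptr = 0
        self.size = 0
        self.rng = np.random.default_rng(seed)

    def __len__(self) -> int:
        return self.size

    def add(self, s, a, r, s2, d) -> None:
        i = self.ptr
        self.obs[i] = s
        self.act[i] = a
        self.rew[i] = r
        self.nobs[i] = s2
        self.done[i] = float(d)
        self.ptr = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int):
        idx = self.rng.integers(0, self.size, size=batch_size)
        return (self.obs[idx], self.act[idx], self.rew[idx], self.nobs[idx], self.done[idx])


class RunningNorm:
    """Running mean/std observation normalizer (Welford), freezable."""

    def __init__(self, dim: int, clip: float = 10.0):
        self.mean = np.zeros(dim, dtype=np.float64)
        self.var = np.ones(dim, dtype=np.float64)
        self.count = 1e-4
        self.clip = clip
        self.frozen = False

    def update(self, x: np.ndarray) -> None:
        if self.frozen:
            return
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        n = x.shape[0]
        bm = x.mean(axis=0)
        bv = x.var(axis=0)
        delta = bm - self.mean
        tot = self.count + n
        self.mean += delta * n / tot
        m_a = self.var * self.count
        m_b = bv * n
        self.var = (m_a + m_b + delta**2 * self.count * n / tot) / tot
        self.count = tot

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=np.float64) - self.mean) / np.sqrt(self.var + 1e-8)
        return np.clip(z, -self.clip, self.clip).astype(np.float32)

    def state(self) -> dict:
        return {"mean": self.mean.copy(), "var": self.var.copy(),
                "count": np.array([self.count]), "frozen": np.array([float(self.frozen)])}

    def load_state(self, st: dict) -> None:
        self.mean = np.asarray(st["mean"], dtype=np.float64).copy()
        self.var = np.asarray(st["var"], dtype=np.float64).copy()
        self.count = float(np.asarray(st["count"]).ravel()[0])
        self.frozen = bool(np.asarray(st["frozen"]).ravel()[0])


@dataclass
class SACConfig:
    gamma: float = 0.99
    tau: float = 0.005
    lr: float = 3e-4
    batch_size: int = 256
    buffer_capacity: int = 1_000_000
    target_entropy: float | None = None  # defaults to -act_dim
    warmup_steps: int = 1000
    update_every: int = 1
    seed: int = 0
    normalize_obs: bool = True

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must be in (0, 1]")


@dataclass
class PPOConfig:
    gamma: float = 0.99
    lam: float = 0.95
    clip_eps: float = 0.2
    lr: float = 3e-4
    epochs: int = 10
    rollout_steps: int = 2048
    minibatch_size: int = 64
    vf_coef: float = 0.5
    ent_coef: float = 0.0
    seed: int = 0
    normalize_obs: bool = True

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.clip_eps <= 0:
            raise ValueError("clip_eps must be positive")


def polyak_update(online: list[np.ndarray], target: list[np.ndarray], tau: float) -> None:
    """target <- tau * online + (1 - tau) * target, elementwise, in place."""
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must be in (0, 1]")
    if len(online) != len(target):
        raise ValueError("parameter lists differ in length")
    for p, t in zip(online, target):
        if p.shape != t.shape:
            raise ValueError("parameter shape mismatch")
        t *= 1.0 - tau
        t += tau * p


def clipped_surrogate(ratio: np.ndarray, advantage: np.ndarray, eps: float) -> np.ndarray:
    """Per-sample PPO objective min(r*A, clip(r, 1-eps, 1+eps)*A)."""
    ratio = np.asarray(ratio, dtype=np.float64)
    advantage = np.asarray(advantage, dtype=np.float64)
    return np.minimum(ratio * advantage, np.clip(ratio, 1.0 - eps, 1.0 + eps) * advantage)


def action_to_angle(a: np.ndarray) -> float:
    """Map a 2-component direction head (u, v) to an angle in (-pi, pi]."""
    return float(math.atan2(a[1], a[0]))


def _config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# SAC
# --------------------------------------------------------------------------


class SACAgent:
    """Entropy-regularized off-policy actor-critic with clipped double-Q.

    The actor outputs a tanh-squashed diagonal Gaussian in [-1, 1]^act_dim.
    For angle-valued actions the two components are interpreted as a
    direction vector and mapped through atan2 by the caller, which avoids
    the wrap discontinuity at +-pi.
    """

    def __init__(self, obs_dim: int, act_dim: int, config: SACConfig | None = None):
        self.cfg = config or SACConfig()
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        rng = np.random.default_rng(self.cfg.seed)
        self.rng = np.random.default_rng(rng.integers(2**31))
        init = lambda: np.random.default_rng(rng.integers(2**31))
        self.actor = MLP(obs_dim, 2 * act_dim, rng=init())
        self.q1 = MLP(obs_dim + act_dim, 1, rng=init())
        self.q2 = MLP(obs_dim + act_dim, 1, rng=init())
        self.q1_targ = self.q1.copy()
        self.q2_targ = self.q2.copy()
        self.log_alpha = np.zeros(1, dtype=np.float32)
        self.target_entropy = (
            self.cfg.target_entropy if self.cfg.target_entropy is not None else -float(act_dim)
        )
        lr = self.cfg.lr
        self.opt_actor = Adam(self.actor.parameters(), lr=lr)
        self.opt_q1 = Adam(self.q1.parameters(), lr=lr)
        self.opt_q2 = Adam(self.q2.parameters(), lr=lr)
        self.opt_alpha = Adam([self.log_alpha], lr=lr)
        self.obs_norm = RunningNorm(obs_dim) if self.cfg.normalize_obs else None
        self.buffer = ReplayBuffer(
            self.cfg.buffer_capacity, obs_dim, act_dim, seed=int(rng.integers(2**31))
        )
        self.updates = 0

    # --- policy -----------------------------------------------------------
    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha[0]))

    def _normalize(self, obs):
        return self.obs_norm(obs) if self.obs_norm is not None else np.asarray(obs, np.float32)

    def _policy_forward(self, z: np.ndarray, xi: np.ndarray):
        """Squashed-Gaussian sample with log-prob; z is the normalized obs batch."""
        out, cache = self.actor.forward(z, need_cache=True)
        A = self.act_dim
        mu = out[..., :A]
        raw = out[..., A:]
        log_std = np.clip(raw, LOG_STD_MIN, LOG_STD_MAX)
        std = np.exp(log_std)
        pre = mu + std * xi
        a = np.tanh(pre)
        # log N(pre; mu, std) with tanh change of variables
        logp = (
            -0.5 * xi**2 - log_std - 0.5 * np.log(2.0 * np.pi)
            - np.log(1.0 - a**2 + 1e-6)
        ).sum(axis=-1)
        aux = {"cache": cache, "mu": mu, "raw": raw, "log_std": log_std,
               "std": std, "xi": xi, "a": a}
        return a, logp, aux

    def select_action(self, obs: np.ndarray, deterministic: bool = False) -> np.ndarray:
        """Action in [-1, 1]^act_dim; deterministic mode returns tanh(mu)."""
        z = self._normalize(obs)
        if deterministic:
            out = self.actor.forward(z)
            return np.tanh(out[..., : self.act_dim])
        xi = self.rng.standard_normal(self.act_dim).astype(np.float32)
        a, _, _ = self._policy_forward(z, xi)
        return a

    def observe(self, s, a, r, s2, done) -> None:
        if self.obs_norm is not None:
            self.obs_norm.update(s)
        self.buffer.add(self._normalize_raw(s), a, r, self._normalize_raw(s2), done)

    def _normalize_raw(self, obs):
        # raw observations are stored; normalization is applied at sample time
        return np.asarray(obs, dtype=np.float32)

    # --- learning ---------------------------------------------------------
    def update(self) -> dict:
        cfg = self.cfg
        if len(self.buffer) < cfg.batch_size:
            return {}
        s, a, r, s2, d = self.buffer.sample(cfg.batch_size)
        z = self._normalize(s)
        z2 = self._normalize(s2)
        B = cfg.batch_size
        A = self.act_dim
        alpha = self.alpha

        # --- critic targets: clipped double-Q with entropy bonus ----------
        xi2 = self.rng.standard_normal((B, A)).astype(np.float32)
        a2, logp2, _ = self._policy_forward(z2, xi2)
        in2 = np.concatenate([z2, a2], axis=1)
        q1t = self.q1_targ.forward(in2)[:, 0]
        q2t = self.q2_targ.forward(in2)[:, 0]
        qmin_t = np.minimum(q1t, q2t)
        y = r + cfg.gamma * (1.0 - d) * (qmin_t - alpha * logp2)

        # --- critic regression --------------------------------------------
        sa = np.concatenate([z, a], axis=1)
        q_losses = []
        for net, opt in ((self.q1, self.opt_q1), (self.q2, self.opt_q2)):
            q, cache = net.forward(sa, need_cache=True)
            err = q[:, 0] - y
            q_losses.append(float(np.mean(err**2)))
            grads, _ = net.backward((2.0 * err / B)[:, None], cache)
            opt.step(grads)

        # --- actor: maximize min-Q + entropy ------------------------------
        xi = self.rng.standard_normal((B, A)).astype(np.float32)
        a_pi, logp_pi, aux = self._policy_forward(z, xi)
        sa_pi = np.concatenate([z, a_pi], axis=1)
        qa1, c1 = self.q1.forward(sa_pi, need_cache=True)
        qa2, c2 = self.q2.forward(sa_pi, need_cache=True)
        take1 = (qa1[:, 0] <= qa2[:, 0]).astype(np.float32)[:, None]
        # d qmin / d action via the selected critic's input gradient
        ones = np.ones((B, 1), np.float32) / B
        dx1 = self.q1.input_gradient(ones, c1)
        dx2 = self.q2.input_gradient(ones, c2)
        dq_da = take1 * dx1[:, self.obs_dim:] + (1.0 - take1) * dx2[:, self.obs_dim:]

        a_sq = aux["a"]
        one_m_a2 = 1.0 - a_sq**2
        # dL/da for L = mean(alpha * logp - qmin)
        dL_da = (alpha / B) * (2.0 * a_sq / (one_m_a2 + 1e-6)) - dq_da / 1.0
        dL_dpre = dL_da * one_m_a2
        dL_dmu = dL_dpre
        dL_dlogstd = dL_dpre * aux["std"] * aux["xi"] - alpha / (B * 1.0)
        # clip mask on log_std
        mask = ((aux["raw"] > LOG_STD_MIN) & (aux["raw"] < LOG_STD_MAX)).astype(np.float32)
        dout = np.concatenate([dL_dmu, dL_dlogstd * mask], axis=1)
        grads, _ = self.actor.backward(dout, aux["cache"])
        actor_loss = float(np.mean(alpha * logp_pi - np.minimum(qa1[:, 0], qa2[:, 0])))
        self.opt_actor.step(grads)

        # --- entropy coefficient ------------------------------------------
        g_alpha = -self.alpha * float(np.mean(logp_pi + self.target_entropy))
        self.opt_alpha.step([np.array([g_alpha], dtype=np.float32)])

        # --- targets -------------------------------------------------------
        polyak_update(self.q1.parameters(), self.q1_targ.parameters(), cfg.tau)
        polyak_update(self.q2.parameters(), self.q2_targ.parameters(), cfg.tau)
        self.updates += 1

        diag = {
            "q1_loss": q_losses[0],
            "q2_loss": q_losses[1],
            "actor_loss": actor_loss,
            "alpha": self.alpha,
            "entropy": float(-np.mean(logp_pi)),
        }
        if not all(np.isfinite(v) for v in diag.values()):
            raise FloatingPointError(f"non-finite SAC loss: {diag}")
        return diag

    # --- persistence ------------------------------------------------------
    def state_arrays(self) -> dict:
        arrays = {"log_alpha": self.log_alpha}
        for name, net in (("actor", self.actor), ("q1", self.q1), ("q2", self.q2),
                          ("q1t", self.q1_targ), ("q2t", self.q2_targ)):
            for i, p in enumerate(net.parameters()):
                arrays[f"{name}_{i}"] = p
        for name, opt in (("oa", self.opt_actor), ("o1", self.opt_q1),
                          ("o2", self.opt_q2), ("oal", self.opt_alpha)):
            st = opt.state()
            for i, m in enumerate(st["m"]):
                arrays[f"{name}_m{i}"] = m
            for i, v in enumerate(st["v"]):
                arrays[f"{name}_v{i}"] = v
            arrays[f"{name}_t"] = np.array([st["t"]])
        if self.obs_norm is not None:
            for k, v in self.obs_norm.state().items():
                arrays[f"norm_{k}"] = v
        arrays["rng_state"] = _rng_to_array(self.rng)
        arrays["buf_rng_state"] = _rng_to_array(self.buffer.rng)
        return arrays

    def load_state_arrays(self, arrays: dict) -> None:
        self.log_alpha = np.asarray(arrays["log_alpha"], dtype=np.float32).copy()
        self.opt_alpha.params = [self.log_alpha]
        for name, net in (("actor", self.actor), ("q1", self.q1), ("q2", self.q2),
                          ("q1t", self.q1_targ), ("q2t", self.q2_targ)):
            n = len(net.parameters())
            net.set_parameters([arrays[f"{name}_{i}"] for i in range(n)])
        self.opt_actor.params = self.actor.parameters()
        self.opt_q1.params = self.q1.parameters()
        self.opt_q2.params = self.q2.parameters()
        for name, opt in (("oa", self.opt_actor), ("o1", self.opt_q1),
                          ("o2", self.opt_q2), ("oal", self.opt_alpha)):
            n = len(opt.params)
            opt.load_state({
                "m": [arrays[f"{name}_m{i}"] for i in range(n)],
                "v": [arrays[f"{name}_v{i}"] for i in range(n)],
                "t": int(np.asarray(arrays[f"{name}_t"]).ravel()[0]),
            })
        if self.obs_norm is not None:
            self.obs_norm.load_state({k[len("norm_"):]: v for k, v in arrays.items()
                                      if k.startswith("norm_")})
        self.rng = _rng_from_array(arrays["rng_state"])
        self.buffer.rng = _rng_from_array(arrays["buf_rng_state"])

    def save(self, path, extra_meta: dict | None = None) -> None:
        meta = {"kind": "sac", "obs_dim": self.obs_dim, "act_dim": self.act_dim,
                "config": asdict(self.cfg), "config_hash": _config_hash(self.cfg)}
        meta.update(extra_meta or {})
        save_checkpoint(path, self.state_arrays(), meta)

    @classmethod
    def load(cls, path) -> "SACAgent":
        arrays, meta = load_checkpoint(path)
        cfg = SACConfig(**{k: v for k, v in meta["config"].items()})
        agent = cls(int(meta["obs_dim"]), int(meta["act_dim"]), cfg)
        agent.load_state_arrays(arrays)
        agent.meta = meta
        return agent


# --------------------------------------------------------------------------
# PPO
# --------------------------------------------------------------------------


def compute_gae(rewards, values, dones, last_value, gamma: float, lam: float):
    """Generalized advantage estimation over one rollout."""
    T = len(rewards)
    adv = np.zeros(T, dtype=np.float64)
    gae = 0.0
    for t in range(T - 1, -1, -1):
        nxt = last_value if t == T - 1 else values[t + 1]
        nonterm = 1.0 - dones[t]
        delta = rewards[t] + gamma * nxt * nonterm - values[t]
        gae = delta + gamma * lam * nonterm * gae
        adv[t] = gae
    returns = adv + values
    return adv, returns


class PPOAgent:
    """Clipped-surrogate on-policy actor-critic with GAE.

    The actor is a diagonal Gaussian with state-independent log-std; actions
    are squashed by the environment into its own bounds.
    """

    def __init__(self, obs_dim: int, act_dim: int, config: PPOConfig | None = None):
        self.cfg = config or PPOConfig()
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        rng = np.random.default_rng(self.cfg.seed)
        self.rng = np.random.default_rng(rng.integers(2**31))
        self.actor = MLP(obs_dim, act_dim, rng=np.random.default_rng(rng.integers(2**31)))
        self.log_std = np.full(act_dim, -0.5, dtype=np.float32)
        self.critic = MLP(obs_dim, 1, rng=np.random.default_rng(rng.integers(2**31)))
        self.opt_actor = Adam(self.actor.parameters() + [self.log_std], lr=self.cfg.lr)
        self.opt_critic = Adam(self.critic.parameters(), lr=self.cfg.lr)
        self.obs_norm = RunningNorm(obs_dim) if self.cfg.normalize_obs else None

    def _normalize(self, obs, update=False):
        if self.obs_norm is None:
            return np.asarray(obs, np.float32)
        if update:
            self.obs_norm.update(obs)
        return self.obs_norm(obs)

    def act(self, obs, deterministic: bool = False):
        """Returns (action, log_prob, value)."""
        z = self._normalize(obs)
        mu = self.actor.forward(z)
        v = float(self.critic.forward(z)[..., 0])
        if deterministic:
            return mu, 0.0, v
        std = np.exp(self.log_std)
        a = mu + std * self.rng.standard_normal(self.act_dim).astype(np.float32)
        logp = float(
            (-0.5 * ((a - mu) / std) ** 2 - self.log_std - 0.5 * np.log(2 * np.pi)).sum()
        )
        return a, logp, v

    def update(self, obs, actions, logp_old, advantages, returns) -> dict:
        """One PPO update (several epochs of minibatch SGD on the rollout)."""
        cfg = self.cfg
        z = np.stack([self._normalize(o) for o in obs]).astype(np.float32)
        actions = np.asarray(actions, dtype=np.float32)
        logp_old = np.asarray(logp_old, dtype=np.float64)
        adv = np.asarray(advantages, dtype=np.float64)
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)
        returns = np.asarray(returns, dtype=np.float64)
        N = len(z)
        idx = np.arange(N)
        diag = {}
        for _ in range(cfg.epochs):
            self.rng.shuffle(idx)
            for start in range(0, N, cfg.minibatch_size):
                mb = idx[start:start + cfg.minibatch_size]
                zb, ab = z[mb], actions[mb]
                advb, retb, lob = adv[mb], returns[mb], logp_old[mb]
                B = len(mb)
                mu, cache = self.actor.forward(zb, need_cache=True)
                std = np.exp(self.log_std)
                u = (ab - mu) / std
                logp = (-0.5 * u**2 - self.log_std - 0.5 * np.log(2 * np.pi)).sum(axis=1)
                ratio = np.exp(logp - lob)
                unclipped = ratio * advb
                clipped = np.clip(ratio, 1 - cfg.clip_eps, 1 + cfg.clip_eps) * advb
                use_unclipped = unclipped <= clipped
                # gradient of -mean(min(...)) wrt logp
                dlogp = np.where(use_unclipped, -ratio * advb, 0.0) / B
                # entropy bonus gradient only touches log_std
                dmu = dlogp[:, None] * (u / std)
                dlogstd = (dlogp[:, None] * (u**2 - 1.0)).sum(axis=0)
                dlogstd -= cfg.ent_coef * np.ones(self.act_dim)  # d(-H)/dlogstd = -1
                grads, _ = self.actor.backward(dmu.astype(np.float32), cache)
                grads.append(dlogstd.astype(np.float32))
                if not all(np.all(np.isfinite(g)) for g in grads):
                    raise FloatingPointError("non-finite PPO actor gradient")
                self.opt_actor.step(grads)

                v, vcache = self.critic.forward(zb, need_cache=True)
                verr = v[:, 0] - retb
                vgrads, _ = self.critic.backward(
                    (cfg.vf_coef * 2.0 * verr / B)[:, None].astype(np.float32), vcache
                )
                self.opt_critic.step(vgrads)
                diag = {
                    "actor_loss": float(-np.mean(np.minimum(unclipped, clipped))),
                    "value_loss": float(np.mean(verr**2)),
                    "approx_kl": float(np.mean(lob - logp)),
                }
        if diag and not all(np.isfinite(v) for v in diag.values()):
            raise FloatingPointError(f"non-finite PPO loss: {diag}")
        return diag

    # --- persistence ------------------------------------------------------
    def state_arrays(self) -> dict:
        arrays = {"log_std": self.log_std}
        for name, net in (("actor", self.actor), ("critic", self.critic)):
            for i, p in enumerate(net.parameters()):
                arrays[f"{name}_{i}"] = p
        for name, opt in (("oa", self.opt_actor), ("oc", self.opt_critic)):
            st = opt.state()
            for i, m in enumerate(st["m"]):
                arrays[f"{name}_m{i}"] = m
            for i, v in enumerate(st["v"]):
                arrays[f"{name}_v{i}"] = v
            arrays[f"{name}_t"] = np.array([st["t"]])
        if self.obs_norm is not None:
            for k, v in self.obs_norm.state().items():
                arrays[f"norm_{k}"] = v
        arrays["rng_state"] = _rng_to_array(self.rng)
        return arrays

    def load_state_arrays(self, arrays: dict) -> None:
        self.log_std = np.asarray(arrays["log_std"], dtype=np.float32).copy()
        for name, net in (("actor", self.actor), ("critic", self.critic)):
            n = len(net.parameters())
            net.set_parameters([arrays[f"{name}_{i}"] for i in range(n)])
        self.opt_actor.params = self.actor.parameters() + [self.log_std]
        self.opt_critic.params = self.critic.parameters()
        for name, opt in (("oa", self.opt_actor), ("oc", self.opt_critic)):
            n = len(opt.params)
            opt.load_state({
                "m": [arrays[f"{name}_m{i}"] for i in range(n)],
                "v": [arrays[f"{name}_v{i}"] for i in range(n)],
                "t": int(np.asarray(arrays[f"{name}_t"]).ravel()[0]),
            })
        if self.obs_norm is not None:
            self.obs_norm.load_state({k[len("norm_"):]: v for k, v in arrays.items()
                                      if k.startswith("norm_")})
        self.rng = _rng_from_array(arrays["rng_state"])

    def save(self, path, extra_meta: dict | None = None) -> None:
        meta = {"kind": "ppo", "obs_dim": self.obs_dim, "act_dim": self.act_dim,
                "config": asdict(self.cfg), "config_hash": _config_hash(self.cfg)}
        meta.update(extra_meta or {})
        save_checkpoint(path, self.state_arrays(), meta)

    @classmethod
    def load(cls, path) -> "PPOAgent":
        arrays, meta = load_checkpoint(path)
        cfg = PPOConfig(**{k: v for k, v in meta["config"].items()})
        agent = cls(int(meta["obs_dim"]), int(meta["act_dim"]), cfg)
        agent.load_state_arrays(arrays)
        agent.meta = meta
        return agent


# --------------------------------------------------------------------------
# checkpoint archive
# --------------------------------------------------------------------------


def _rng_to_array(rng: np.random.Generator) -> np.ndarray:
    payload = json.dumps(rng.bit_generator.state)
    return np.frombuffer(payload.encode(), dtype=np.uint8).copy()


def _rng_from_array(arr: np.ndarray) -> np.random.Generator:
    state = json.loads(bytes(np.asarray(arr, dtype=np.uint8)).decode())
    rng = np.random.default_rng()
    rng.bit_generator.state = state
    return rng


def save_checkpoint(path, arrays: dict, meta: dict) -> None:
    """Write a named npz archive of weights/optimizer/normalizer + JSON meta."""
    meta_arr = np.frombuffer(json.dumps(meta, default=float).encode(), dtype=np.uint8).copy()
    np.savez(path, __meta__=meta_arr, **arrays)


def load_checkpoint(path):
    with np.load(path) as z:
        arrays = {k: z[k].copy() for k in z.files if k != "__meta__"}
        meta = json.loads(bytes(z["__meta__"]).decode())
    return arrays, meta
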