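"""Gait-level control: swim in a designated target direction theta_T.

Two interchangeable controllers share one interface
``controller(state, theta_T) -> Actuation`` (plus ``reset()``):

* :class:`OracleGaitController` -- a deterministic finite-state script
  built from two closed strokes: the four-phase contract/extend
  translation stroke (net displacement along the body axis) and a
  quadrature hinge/link turning stroke (net body rotation).  It lets the
  navigation stage be developed and tested independently of gait training.
* :class:`PPOGaitController` -- a clipped-surrogate policy-gradient (PPO)
  policy trained on the same task, mapping the swimmer configuration
  (L1, L2, thetaA) and the heading error to actuation rates.

Because the swimmer has no intrinsic head or tail, a target direction can
be reached by aligning either end; :func:`resolve_head_tail` picks the
smaller turn, breaking exact ties counterclockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hydrodynamics import (
    Actuation,
    HydroParams,
    SwimmerState,
    L_MIN,
    L_MAX,
    THETA_A_MIN,
    THETA_A_MAX,
    step,
    wrap_angle,
    wrap_positive,
)
from .rl_core import PPOAgent, PPOConfig, compute_gae

__all__ = [
    "GaitObservation",
    "resolve_head_tail",
    "gait_observation",
    "gait_env_step",
    "GaitEnv",
    "OracleGaitController",
    "PPOGaitController",
    "train_gait_predictor",
    "evaluate_gait_policy",
]

# measured stroke outputs of the swimmer at R=0.1, dt=0.1 (regression-tested
# in the hydrodynamics suite): net turn per inner step of hinge swing in the
# quadrature turning stroke, used to size turn cycles.
_TURN_PER_SWING_STEP = 0.0085


@dataclass(frozen=True)
class GaitObservation:
    """Configuration plus signed heading error seen by the gait policy."""

    L1: float
    L2: float
    thetaA: float
    theta_err: float  # wrapped into (-pi, pi]

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.L1, self.L2, self.thetaA,
             math.cos(self.theta_err), math.sin(self.theta_err)],
            dtype=np.float32,
        )

    @staticmethod
    def dim() -> int:
        return 5


def resolve_head_tail(theta_c: float, theta_T: float) -> tuple[float, bool]:
    """Smaller-turn alignment of either end of the swimmer with theta_T.

    Returns (turn, tail_leads): the signed turn to apply to the body and
    whether the tail end (the -theta_c direction) leads afterwards.  Exact
    ties (90 degree turns) resolve counterclockwise (positive turn).
    """
    d_head = wrap_angle(theta_T - theta_c)
    d_tail = wrap_angle(theta_T - theta_c - math.pi)
    if abs(d_head) < abs(d_tail):
        return d_head, False
    if abs(d_tail) < abs(d_head):
        return d_tail, True
    # tie: prefer the counterclockwise (positive) turn
    return (d_head, False) if d_head >= 0.0 else (d_tail, True)


def gait_observation(state: SwimmerState, theta_T: float) -> GaitObservation:
    return GaitObservation(
        L1=state.L1, L2=state.L2, thetaA=wrap_positive(state.thetaA),
        theta_err=wrap_angle(theta_T - state.theta_c),
    )


def action_to_actuation(action: np.ndarray) -> Actuation:
    """Map a policy action in [-1, 1]^3 onto the capped actuation rates."""
    a = np.clip(np.asarray(action, dtype=float), -1.0, 1.0)
    return Actuation(float(a[0]), float(a[1]), float(a[2]))


def gait_env_step(
    state: SwimmerState,
    action: np.ndarray,
    theta_T: float,
    params: HydroParams = HydroParams(),
    overshoot_coef: float = 0.0,
):
    """One inner step of the gait task.

    Reward is the centroid displacement projected on the unit vector of
    theta_T, optionally minus ``overshoot_coef`` times the increase in
    heading-error magnitude.
    """
    act = action_to_actuation(action)
    err_before = abs(wrap_angle(theta_T - state.theta_c))
    nxt = step(state, act, params)
    disp = nxt.r_c - state.r_c
    reward = float(disp[0] * math.cos(theta_T) + disp[1] * math.sin(theta_T))
    if overshoot_coef:
        err_after = abs(wrap_angle(theta_T - nxt.theta_c))
        reward -= overshoot_coef * max(0.0, err_after - err_before)
    return nxt, reward, gait_observation(nxt, theta_T)


class GaitEnv:
    """Episodic gait-training environment for the PPO predictor.

    Each episode draws a random valid configuration and a uniform target
    direction; the policy actuates for ``episode_steps`` inner steps.
    """

    def __init__(self, params: HydroParams = HydroParams(), episode_steps: int = 500,
                 seed: int = 0, overshoot_coef: float = 0.0):
        self.params = params
        self.episode_steps = episode_steps
        self.rng = np.random.default_rng(seed)
        self.overshoot_coef = overshoot_coef
        self.state: SwimmerState | None = None
        self.theta_T = 0.0
        self.t = 0

    obs_dim = GaitObservation.dim()
    act_dim = 3

    def reset(self) -> np.ndarray:
        r = self.rng
        self.state = SwimmerState(
            r1=np.zeros(2),
            theta1=r.uniform(-math.pi, math.pi),
            L1=r.uniform(L_MIN, L_MAX),
            L2=r.uniform(L_MIN, L_MAX),
            thetaA=r.uniform(THETA_A_MIN, THETA_A_MAX),
        )
        self.theta_T = r.uniform(-math.pi, math.pi)
        self.t = 0
        return gait_observation(self.state, self.theta_T).as_array()

    def step(self, action: np.ndarray):
        self.state, reward, obs = gait_env_step(
            self.state, action, self.theta_T, self.params, self.overshoot_coef
        )
        self.t += 1
        done = self.t >= self.episode_steps
        return obs.as_array(), reward, done


# --------------------------------------------------------------------------
# scripted oracle controller
# --------------------------------------------------------------------------


class OracleGaitController:
    """Deterministic stroke script implementing the gait interface.

    At each closed-stroke boundary the controller re-homes the shape
    (L1 = L2 = 1, thetaA = pi), resolves which end should lead, and either

    * executes a quadrature turning cycle -- swing the hinge, contract
      link 1, swing back, extend link 1 -- whose swing length is sized to
      the remaining turn, or
    * executes the four-phase translation stroke (contract L1, contract
      L2, extend L1, extend L2 for head-leading motion; link order swapped
      to swim tail-first).

    Both strokes are closed in shape space, so the controller never drives
    the configuration against its bounds except transiently at turnaround.
    """

    def __init__(self, params: HydroParams = HydroParams(), turn_threshold: float = 0.2,
                 phase_steps: int = 4, max_swing_steps: int = 10):
        self.params = params
        self.turn_threshold = turn_threshold
        self.phase_steps = phase_steps
        self.max_swing_steps = max_swing_steps
        self._plan: list[Actuation] = []

    def reset(self) -> None:
        self._plan = []

    def _home_rates(self, state: SwimmerState) -> Actuation | None:
        dt = self.params.dt
        tol = 1e-6
        dL1 = (L_MAX - state.L1) / dt
        dL2 = (L_MAX - state.L2) / dt
        dA = (math.pi - wrap_positive(state.thetaA)) / dt
        if abs(dL1) < tol and abs(dL2) < tol and abs(dA) < tol:
            return None
        clip = lambda v: max(-1.0, min(1.0, v))
        return Actuation(clip(dL1), clip(dL2), clip(dA))

    def _plan_turn(self, turn: float) -> list[Actuation]:
        n_swing = int(round(abs(turn) / _TURN_PER_SWING_STEP))
        n_swing = max(2, min(self.max_swing_steps, n_swing))
        s = 1.0 if turn >= 0 else -1.0
        n = self.phase_steps
        return (
            [Actuation(0, 0, s)] * n_swing
            + [Actuation(-1, 0, 0)] * n
            + [Actuation(0, 0, -s)] * n_swing
            + [Actuation(1, 0, 0)] * n
        )

    def _plan_translate(self, tail_leads: bool) -> list[Actuation]:
        n = self.phase_steps
        if not tail_leads:  # net displacement along +theta_c
            return ([Actuation(-1, 0, 0)] * n + [Actuation(0, -1, 0)] * n
                    + [Actuation(1, 0, 0)] * n + [Actuation(0, 1, 0)] * n)
        return ([Actuation(0, -1, 0)] * n + [Actuation(-1, 0, 0)] * n
                + [Actuation(0, 1, 0)] * n + [Actuation(1, 0, 0)] * n)

    def __call__(self, state: SwimmerState, theta_T: float) -> Actuation:
        if not self._plan:
            home = self._home_rates(state)
            if home is not None:
                return home
            turn, tail_leads = resolve_head_tail(state.theta_c, theta_T)
            if abs(turn) > self.turn_threshold:
                self._plan = self._plan_turn(turn)
            else:
                self._plan = self._plan_translate(tail_leads)
        return self._plan.pop(0)


# --------------------------------------------------------------------------
# PPO gait predictor
# --------------------------------------------------------------------------


class PPOGaitController:
    """Greedy PPO gait policy behind the shared controller interface."""

    def __init__(self, agent: PPOAgent):
        self.agent = agent

    def reset(self) -> None:
        pass

    def __call__(self, state: SwimmerState, theta_T: float) -> Actuation:
        obs = gait_observation(state, theta_T).as_array()
        a, _, _ = self.agent.act(obs, deterministic=True)
        return action_to_actuation(np.tanh(a))

    @classmethod
    def from_checkpoint(cls, path) -> "PPOGaitController":
        return cls(PPOAgent.load(path))


def _collect_rollout(env: GaitEnv, agent: PPOAgent, steps: int, obs):
    """On-policy rollout of fixed length; returns arrays + final bootstrap."""
    O, A, LP, R, D, V = [], [], [], [], [], []
    ep_rewards, ep_ret = [], 0.0
    for _ in range(steps):
        a, logp, v = agent.act(obs)
        if agent.obs_norm is not None:
            agent.obs_norm.update(obs)
        nobs, r, done = env.step(np.tanh(a))
        O.append(obs); A.append(a); LP.append(logp); R.append(r); D.append(done); V.append(v)
        ep_ret += r
        if done:
            ep_rewards.append(ep_ret)
            ep_ret = 0.0
            nobs = env.reset()
        obs = nobs
    _, _, last_v = agent.act(obs, deterministic=True)
    return (np.array(O, np.float32), np.array(A, np.float32), np.array(LP),
            np.array(R), np.array(D, np.float64), np.array(V), last_v, obs, ep_rewards)


def train_gait_predictor(
    config: PPOConfig | None = None,
    params: HydroParams = HydroParams(),
    seed: int = 0,
    n_updates: int = 60,
    episode_steps: int = 500,
    progress: bool = False,
) -> tuple[PPOAgent, list[float]]:
    """Train the PPO locomotory-gait predictor.

    Returns the trained agent and the per-episode reward history.  The
    greedy policy can be wrapped in :class:`PPOGaitController`.
    """
    cfg = config or PPOConfig(seed=seed)
    env = GaitEnv(params, episode_steps=episode_steps, seed=seed + 1)
    agent = PPOAgent(GaitEnv.obs_dim, GaitEnv.act_dim, cfg)
    obs = env.reset()
    history: list[float] = []
    for u in range(n_updates):
        O, A, LP, R, D, V, last_v, obs, eps = _collect_rollout(env, agent, cfg.rollout_steps, obs)
        adv, ret = compute_gae(R, V, D, last_v, cfg.gamma, cfg.lam)
        agent.update(O, A, LP, adv, ret)
        history.extend(eps)
        if progress:
            print(f"update {u + 1}/{n_updates}: mean step reward {R.mean():.5f}")
    return agent, history


def evaluate_gait_policy(
    controller,
    params: HydroParams = HydroParams(),
    n_starts: int = 50,
    steps: int = 500,
    seed: int = 0,
):
    """Greedy evaluation from random configurations and uniform theta_T.

    Returns (mean displacement rate along theta_T, mean terminal |theta_err|),
    where the terminal error uses the head/tail-resolved effective heading.
    """
    rng = np.random.default_rng(seed)
    rates, errs = [], []
    for _ in range(n_starts):
        st = SwimmerState(
            r1=np.zeros(2),
            theta1=rng.uniform(-math.pi, math.pi),
            L1=rng.uniform(L_MIN, L_MAX),
            L2=rng.uniform(L_MIN, L_MAX),
            thetaA=rng.uniform(THETA_A_MIN, THETA_A_MAX),
        )
        theta_T = rng.uniform(-math.pi, math.pi)
        if hasattr(controller, "reset"):
            controller.reset()
        r0 = st.r_c.copy()
        for _ in range(steps):
            st = step(st, controller(st, theta_T), params)
        disp = st.r_c - r0
        rates.append(
            (disp[0] * math.cos(theta_T) + disp[1] * math.sin(theta_T)) / (steps * params.dt)
        )
        turn, _ = resolve_head_tail(st.theta_c, theta_T)
        errs.append(abs(turn))
    return float(np.mean(rates)), float(np.mean(errs))
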