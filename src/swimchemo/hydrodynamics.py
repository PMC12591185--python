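"""Stokesian dynamics of the reconfigurable three-sphere swimmer.

The swimmer is three rigid spheres of radius ``R`` joined by two extensible
links of lengths ``L1``, ``L2`` whose relative angle ``thetaA`` can be
actuated.  At zero Reynolds number sphere velocities and the hydrodynamic
forces on them are linearly related through the Oseen-Burger mobility
tensor; closing the system with the kinematic link constraints and the
force-free / torque-free conditions yields a 7x7 linear solve in the three
sphere forces and the body rotation rate of link 1.

All quantities are dimensionless: lengths in units of the maximum link
length ``L``, rates in units of the characteristic actuation rate ``V_c``,
time in units of ``L / V_c`` and viscosity ``mu = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "L_MIN",
    "L_MAX",
    "THETA_A_MIN",
    "THETA_A_MAX",
    "OverlapError",
    "SingularConfigurationError",
    "HydroParams",
    "SwimmerState",
    "Actuation",
    "DynamicsSolution",
    "oseen_block",
    "grand_mobility",
    "solve_dynamics",
    "project_actuation",
    "step",
    "run_gait_sequence",
    "write_trajectory",
    "read_trajectory",
]

L_MIN = 0.6
L_MAX = 1.0
THETA_A_MIN = 2.0 * math.pi / 3.0
THETA_A_MAX = 4.0 * math.pi / 3.0

_BOUND_TOL = 1e-9


class OverlapError(ValueError):
    """Two distinct spheres are closer than one diameter (Oseen level invalid)."""


class SingularConfigurationError(RuntimeError):
    """The 7x7 mobility/constraint system is numerically singular."""


def wrap_angle(a: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    a = math.remainder(a, 2.0 * math.pi)
    if a <= -math.pi:
        a += 2.0 * math.pi
    return a


def wrap_positive(a: float) -> float:
    """Wrap an angle into (0, 2*pi]."""
    a = a % (2.0 * math.pi)
    if a == 0.0:
        a = 2.0 * math.pi
    return a


@dataclass(frozen=True)
class HydroParams:
    """Physical and numerical parameters of the hydrodynamic model.

    R : sphere radius (units of L).  mu : dynamic viscosity (set to 1 in the
    nondimensional scheme).  dt : inner (gait) time step.
    """

    R: float = 0.1
    mu: float = 1.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.R <= 0 or self.mu <= 0 or self.dt <= 0:
            raise ValueError("R, mu and dt must be positive")
        if 2.0 * self.R >= L_MIN:
            raise ValueError("spheres would overlap at maximum contraction (2R >= 0.6)")


@dataclass
class SwimmerState:
    """Generalized coordinates of the swimmer.

    The state is carried as (r1, theta1, L1, L2, thetaA); sphere positions
    r2, r3 are always rebuilt from these so the kinematic constraints hold
    exactly (no drift).

    thetaA is the hinge angle between the two links at sphere 2: thetaA = pi
    is the extended collinear shape, and the actuation range [2pi/3, 4pi/3]
    keeps the outer spheres well separated.  The world-frame direction of
    link 2 is therefore theta2 = theta1 + thetaA - pi.
    """

    r1: np.ndarray
    theta1: float
    L1: float
    L2: float
    thetaA: float

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=float).copy()
        if self.r1.shape != (2,):
            raise ValueError("r1 must be a 2-vector")

    # --- derived geometry -------------------------------------------------
    @property
    def theta2(self) -> float:
        return self.theta1 + self.thetaA - math.pi

    @property
    def e1(self) -> np.ndarray:
        return np.array([math.cos(self.theta1), math.sin(self.theta1)])

    @property
    def e2(self) -> np.ndarray:
        return np.array([math.cos(self.theta2), math.sin(self.theta2)])

    @property
    def r2(self) -> np.ndarray:
        return self.r1 + self.L1 * self.e1

    @property
    def r3(self) -> np.ndarray:
        return self.r2 + self.L2 * self.e2

    @property
    def r_c(self) -> np.ndarray:
        return (self.r1 + self.r2 + self.r3) / 3.0

    @property
    def theta_c(self) -> float:
        d = self.r_c - self.r1
        return math.atan2(d[1], d[0])

    def positions(self) -> np.ndarray:
        """Stacked sphere positions, shape (3, 2)."""
        return np.stack([self.r1, self.r2, self.r3])

    def validate(self) -> None:
        if not (L_MIN - _BOUND_TOL <= self.L1 <= L_MAX + _BOUND_TOL):
            raise ValueError(f"L1={self.L1} outside [{L_MIN}, {L_MAX}]")
        if not (L_MIN - _BOUND_TOL <= self.L2 <= L_MAX + _BOUND_TOL):
            raise ValueError(f"L2={self.L2} outside [{L_MIN}, {L_MAX}]")
        a = wrap_positive(self.thetaA)
        if not (THETA_A_MIN - _BOUND_TOL <= a <= THETA_A_MAX + _BOUND_TOL):
            raise ValueError(f"thetaA={a} outside [{THETA_A_MIN}, {THETA_A_MAX}]")

    def copy(self) -> "SwimmerState":
        return replace(self, r1=self.r1.copy())

    @classmethod
    def from_centroid(
        cls,
        r_c: Sequence[float],
        theta_c: float,
        L1: float = 1.0,
        L2: float = 1.0,
        thetaA: float = math.pi,
    ) -> "SwimmerState":
        """Build a state with prescribed centroid and orientation.

        theta_c = arg(r_c - r1) fixes theta1 up to the body-frame angle of
        the centroid offset, solved here in closed form.
        """
        # r_c - r1 = (2 L1 e(th1) + L2 e(th1 + thA - pi)) / 3
        off = 2.0 * L1 + L2 * complex(math.cos(thetaA - math.pi), math.sin(thetaA - math.pi))
        theta1 = theta_c - math.atan2(off.imag, off.real)
        mag = abs(off) / 3.0
        r_c = np.asarray(r_c, dtype=float)
        r1 = r_c - mag * np.array([math.cos(theta_c), math.sin(theta_c)])
        return cls(r1=r1, theta1=theta1, L1=L1, L2=L2, thetaA=thetaA)


@dataclass(frozen=True)
class Actuation:
    """Link extension rates (units V_c) and relative-angle rate (units V_c/L)."""

    dL1: float = 0.0
    dL2: float = 0.0
    dThetaA: float = 0.0

    def __post_init__(self) -> None:
        cap = 1.0 + 1e-12
        if abs(self.dL1) > cap or abs(self.dL2) > cap or abs(self.dThetaA) > cap:
            raise ValueError("actuation rates are capped at magnitude 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.dL1, self.dL2, self.dThetaA])


@dataclass
class DynamicsSolution:
    """Forces, body rotation rate and velocities at one instant."""

    F: np.ndarray  # (3, 2) hydrodynamic forces
    dTheta1: float
    V: np.ndarray  # (3, 2) sphere velocities


def oseen_block(ri, rj, R: float = 0.1, mu: float = 1.0) -> np.ndarray:
    """One 2x2 block of the Oseen-Burger mobility tensor.

    Self term I/(6 pi mu R); cross term (1/(8 pi mu |rij|)) (I + rij rij / |rij|^2).
    Distinct spheres must be separated by more than one diameter.
    """
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    d = ri - rj
    dist = float(np.hypot(d[0], d[1]))
    if dist == 0.0:
        return np.eye(2) / (6.0 * math.pi * mu * R)
    if dist <= 2.0 * R:
        raise OverlapError(f"sphere separation {dist:.4g} <= 2R = {2 * R:.4g}")
    return (np.eye(2) + np.outer(d, d) / dist**2) / (8.0 * math.pi * mu * dist)


def grand_mobility(state: SwimmerState, params: HydroParams) -> np.ndarray:
    """Assembled 6x6 mobility matrix of the three spheres (symmetric, SPD)."""
    pos = state.positions()
    H = np.zeros((6, 6))
    for i in range(3):
        for j in range(3):
            H[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = oseen_block(
                pos[i], pos[j], params.R, params.mu
            )
    return H


@njit(cache=True)
def _solve_core(r1, r2, r3, theta1, L1, L2, thetaA, dL1, dL2, dthA, R, mu):
    """Assemble and solve the 7x7 system in (F1, F2, F3, dtheta1).

    Rows 0-1: relative velocity of link 1 (V2 - V1 = dL1 e1 + L1 dth1 e1p)
    Rows 2-3: relative velocity of link 2 with dtheta2 = dtheta1 + dthA
    Rows 4-5: force-free
    Row 6:    torque-free about the centroid
    Returns (ok, F(3,2), dtheta1, V(3,2)); ok=False flags overlap.
    """
    pos = np.empty((3, 2))
    pos[0] = r1
    pos[1] = r2
    pos[2] = r3
    H = np.empty((3, 3, 2, 2))
    for i in range(3):
        for j in range(3):
            if i == j:
                c = 1.0 / (6.0 * math.pi * mu * R)
                H[i, j, 0, 0] = c
                H[i, j, 0, 1] = 0.0
                H[i, j, 1, 0] = 0.0
                H[i, j, 1, 1] = c
            else:
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dist = math.sqrt(dx * dx + dy * dy)
                if dist <= 2.0 * R:
                    return False, np.zeros((3, 2)), 0.0, np.zeros((3, 2))
                c = 1.0 / (8.0 * math.pi * mu * dist)
                d2 = dist * dist
                H[i, j, 0, 0] = c * (1.0 + dx * dx / d2)
                H[i, j, 0, 1] = c * (dx * dy / d2)
                H[i, j, 1, 0] = c * (dx * dy / d2)
                H[i, j, 1, 1] = c * (1.0 + dy * dy / d2)

    theta2 = theta1 + thetaA - math.pi
    e1 = np.array([math.cos(theta1), math.sin(theta1)])
    e2 = np.array([math.cos(theta2), math.sin(theta2)])
    e1p = np.array([-e1[1], e1[0]])
    e2p = np.array([-e2[1], e2[0]])

    A = np.zeros((7, 7))
    b = np.zeros(7)
    # link 1 kinematics
    for j in range(3):
        for k in range(2):
            for m in range(2):
                A[k, 2 * j + m] = H[1, j, k, m] - H[0, j, k, m]
    A[0, 6] = -L1 * e1p[0]
    A[1, 6] = -L1 * e1p[1]
    b[0] = dL1 * e1[0]
    b[1] = dL1 * e1[1]
    # link 2 kinematics
    for j in range(3):
        for k in range(2):
            for m in range(2):
                A[2 + k, 2 * j + m] = H[2, j, k, m] - H[1, j, k, m]
    A[2, 6] = -L2 * e2p[0]
    A[3, 6] = -L2 * e2p[1]
    b[2] = dL2 * e2[0] + L2 * dthA * e2p[0]
    b[3] = dL2 * e2[1] + L2 * dthA * e2p[1]
    # force-free
    for j in range(3):
        A[4, 2 * j] = 1.0
        A[5, 2 * j + 1] = 1.0
    # torque-free about the centroid
    cx = (pos[0, 0] + pos[1, 0] + pos[2, 0]) / 3.0
    cy = (pos[0, 1] + pos[1, 1] + pos[2, 1]) / 3.0
    for j in range(3):
        A[6, 2 * j] = -(pos[j, 1] - cy)
        A[6, 2 * j + 1] = pos[j, 0] - cx

    u = np.linalg.solve(A, b)
    F = u[:6].reshape(3, 2)
    w = u[6]
    V = np.zeros((3, 2))
    for i in range(3):
        for j in range(3):
            for k in range(2):
                V[i, k] += H[i, j, k, 0] * F[j, 0] + H[i, j, k, 1] * F[j, 1]
    return True, F, w, V


def solve_dynamics(
    state: SwimmerState, act: Actuation, params: HydroParams = HydroParams()
) -> DynamicsSolution:
    """Solve for forces, sphere velocities and the body rotation rate.

    Raises OverlapError for invalid configurations and
    SingularConfigurationError if the linear system cannot be solved.
    """
    try:
        ok, F, w, V = _solve_core(
            state.r1,
            state.r2,
            state.r3,
            state.theta1,
            state.L1,
            state.L2,
            state.thetaA,
            act.dL1,
            act.dL2,
            act.dThetaA,
            params.R,
            params.mu,
        )
    except Exception as exc:  # numba raises on singular systems
        raise SingularConfigurationError(str(exc)) from exc
    if not ok:
        raise OverlapError("sphere separation <= 2R in solve_dynamics")
    if not (np.all(np.isfinite(F)) and math.isfinite(w)):
        raise SingularConfigurationError("non-finite dynamics solution")
    return DynamicsSolution(F=F, dTheta1=float(w), V=V)


@njit(cache=True)
def _project_rates(L1, L2, thetaA, dL1, dL2, dthA, dt):
    """Zero actuation components whose Euler step would leave the bounds."""
    tol = 1e-9
    lo_a = 2.0 * math.pi / 3.0
    hi_a = 4.0 * math.pi / 3.0
    if L1 + dL1 * dt > 1.0 + tol or L1 + dL1 * dt < 0.6 - tol:
        dL1 = 0.0
    if L2 + dL2 * dt > 1.0 + tol or L2 + dL2 * dt < 0.6 - tol:
        dL2 = 0.0
    if thetaA + dthA * dt > hi_a + tol or thetaA + dthA * dt < lo_a - tol:
        dthA = 0.0
    return dL1, dL2, dthA


def project_actuation(state: SwimmerState, act: Actuation, params: HydroParams) -> Actuation:
    """Bound projection: rates that would violate a link/angle bound are zeroed."""
    dL1, dL2, dthA = _project_rates(
        state.L1, state.L2, wrap_positive(state.thetaA), act.dL1, act.dL2, act.dThetaA, params.dt
    )
    if (dL1, dL2, dthA) == (act.dL1, act.dL2, act.dThetaA):
        return act
    return Actuation(dL1, dL2, dthA)


@njit(cache=True)
def _step_core(gen, dL1, dL2, dthA, R, mu, dt):
    """One projected explicit-Euler step on the generalized coordinates.

    gen = (x1, y1, theta1, L1, L2, thetaA).  Returns (ok, new_gen).
    """
    x1, y1, theta1, L1, L2, thetaA = gen
    dL1, dL2, dthA = _project_rates(L1, L2, thetaA, dL1, dL2, dthA, dt)
    e1x = math.cos(theta1)
    e1y = math.sin(theta1)
    th2 = theta1 + thetaA - math.pi
    e2x = math.cos(th2)
    e2y = math.sin(th2)
    r1 = np.array([x1, y1])
    r2 = np.array([x1 + L1 * e1x, y1 + L1 * e1y])
    r3 = np.array([r2[0] + L2 * e2x, r2[1] + L2 * e2y])
    ok, F, w, V = _solve_core(r1, r2, r3, theta1, L1, L2, thetaA, dL1, dL2, dthA, R, mu)
    if not ok:
        return False, gen
    out = np.empty(6)
    out[0] = x1 + V[0, 0] * dt
    out[1] = y1 + V[0, 1] * dt
    out[2] = theta1 + w * dt
    out[3] = min(max(L1 + dL1 * dt, 0.6), 1.0)
    out[4] = min(max(L2 + dL2 * dt, 0.6), 1.0)
    out[5] = min(max(thetaA + dthA * dt, 2.0 * math.pi / 3.0), 4.0 * math.pi / 3.0)
    return True, out


def _gen_coords(state: SwimmerState) -> np.ndarray:
    return np.array(
        [state.r1[0], state.r1[1], state.theta1, state.L1, state.L2, wrap_positive(state.thetaA)]
    )


def _from_gen(gen: np.ndarray) -> SwimmerState:
    return SwimmerState(
        r1=gen[:2].copy(), theta1=float(gen[2]), L1=float(gen[3]), L2=float(gen[4]),
        thetaA=float(gen[5]),
    )


def step(state: SwimmerState, act: Actuation, params: HydroParams = HydroParams()) -> SwimmerState:
    """Advance the swimmer by one inner time step (projected explicit Euler).

    Sphere positions of the returned state are rebuilt from the generalized
    coordinates, so the link-reconstruction invariant holds to machine
    precision at every step.
    """
    ok, gen = _step_core(_gen_coords(state), act.dL1, act.dL2, act.dThetaA,
                         params.R, params.mu, params.dt)
    if not ok:
        raise OverlapError("sphere separation <= 2R during step")
    return _from_gen(gen)


def run_gait_sequence(
    state: SwimmerState, acts: Iterable[Actuation], params: HydroParams = HydroParams()
) -> list[SwimmerState]:
    """Integrate a sequence of actuations; returns len(acts)+1 states."""
    acts = list(acts)
    if not acts:
        raise ValueError("actuation sequence must be nonempty")
    out = [state.copy()]
    cur = _gen_coords(state)
    for act in acts:
        ok, cur = _step_core(cur, act.dL1, act.dL2, act.dThetaA, params.R, params.mu, params.dt)
        if not ok:
            raise OverlapError("sphere separation <= 2R during gait sequence")
        out.append(_from_gen(cur))
    return out


# --- trajectory I/O -------------------------------------------------------

_TRAJ_COLUMNS = [
    "t", "x1", "y1", "x2", "y2", "x3", "y3", "L1", "L2",
    "theta1", "theta2", "thetaA", "xc", "yc", "theta_c",
]


def write_trajectory(path, times: Sequence[float], states: Sequence[SwimmerState]) -> None:
    """Write a trajectory as CSV (12 significant digits, mandatory header)."""
    if len(times) != len(states):
        raise ValueError("times and states must have equal length")
    with open(path, "w") as fh:
        fh.write(",".join(_TRAJ_COLUMNS) + "\n")
        for t, s in zip(times, states):
            row = [
                t, s.r1[0], s.r1[1], s.r2[0], s.r2[1], s.r3[0], s.r3[1],
                s.L1, s.L2, s.theta1, s.theta2, wrap_positive(s.thetaA),
                s.r_c[0], s.r_c[1], s.theta_c,
            ]
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def read_trajectory(path):
    """Read a trajectory CSV; returns (times, states)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    states = [
        SwimmerState(
            r1=np.array([row.x1, row.y1]), theta1=row.theta1,
            L1=row.L1, L2=row.L2, thetaA=row.thetaA,
        )
        for row in df.itertuples()
    ]
    return df["t"].to_numpy(), states
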