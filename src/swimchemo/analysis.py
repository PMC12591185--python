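"""Behavioral analysis: run/tumble/wander classification and trajectory metrics.

The navigator's emergent strategy mirrors bacterial chemotaxis: *runs*
(smooth translation with a nearly constant target direction), *tumbles*
(rapid resampling of theta_T to reorient) and *wander* (low-net-motion
local search near a concentration maximum).  The classifier works on
windows of sensing events using two thresholds: the largest wrapped jump
in theta_T within the window (tumble) and the net centroid displacement
(wander).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass

import numpy as np

from .hydrodynamics import wrap_angle

__all__ = [
    "Trajectory",
    "ModeThresholds",
    "classify_modes",
    "mode_fractions",
    "radial_histogram",
    "reaching_time",
    "CENSORED",
    "write_modes_csv",
    "write_histogram_json",
]

MODES = ("run", "tumble", "wander")
CENSORED = "censored"


@dataclass
class Trajectory:
    """Uniformly sampled series at sensing events (outer timescale)."""

    t: np.ndarray
    r_c: np.ndarray  # (N, 2)
    theta_c: np.ndarray
    L1: np.ndarray
    L2: np.ndarray
    thetaA: np.ndarray
    theta_T: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        n = len(self.t)
        for name in ("theta_c", "L1", "L2", "thetaA", "theta_T", "C"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if self.r_c.shape != (n, 2):
            raise ValueError("r_c must have shape (N, 2)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_record(cls, rec: dict) -> "Trajectory":
        return cls(
            t=np.asarray(rec["t"], float),
            r_c=np.column_stack([rec["x"], rec["y"]]).astype(float),
            theta_c=np.asarray(rec["theta_c"], float),
            L1=np.asarray(rec["L1"], float),
            L2=np.asarray(rec["L2"], float),
            thetaA=np.asarray(rec["thetaA"], float),
            theta_T=np.asarray(rec["theta_T"], float),
            C=np.asarray(rec["C"], float),
        )


@dataclass(frozen=True)
class ModeThresholds:
    """Mode boundaries: tumble if any |d theta_T| jump exceeds phi_tumble,
    else wander if the window's net displacement is below d_wander."""

    phi_tumble: float = math.pi / 3.0
    d_wander: float = 0.2


def classify_modes(traj: Trajectory, window: int = 5,
                   thresholds: ModeThresholds = ModeThresholds()) -> list[str]:
    """Per-window mode labels over consecutive windows of sensing events.

    Invariant to global rotation and translation of the trajectory (only
    theta_T increments and displacement norms enter).
    """
    if window < 2:
        raise ValueError("window must span at least 2 sensing events")
    n = len(traj)
    if n < window + 1:
        raise ValueError("trajectory shorter than one window")
    labels: list[str] = []
    for start in range(0, n - window, window):
        end = start + window
        th = traj.theta_T[start:end + 1]
        th = th[np.isfinite(th)]
        max_jump = 0.0
        for a, b in zip(th[:-1], th[1:]):
            max_jump = max(max_jump, abs(wrap_angle(b - a)))
        disp = np.linalg.norm(traj.r_c[end] - traj.r_c[start])
        if max_jump > thresholds.phi_tumble:
            labels.append("tumble")
        elif disp < thresholds.d_wander:
            labels.append("wander")
        else:
            labels.append("run")
    return labels


def mode_fractions(labels) -> dict[str, float]:
    """Fraction of windows in each mode; fractions sum to one."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels")
    n = len(labels)
    return {m: labels.count(m) / n for m in MODES}


def radial_histogram(angles, n_bins: int = 24):
    """Min-max normalized angular histogram of target directions.

    Counts per equal-width bin over (-pi, pi] are mapped to
    (n - n_min) / (n_max - n_min); if every bin holds the same count the
    intensities are all zero by convention.  Returns (bin_edges,
    intensities).
    """
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise ValueError("no angles to histogram")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    wrapped = np.array([wrap_angle(a) for a in angles])
    edges = np.linspace(-math.pi, math.pi, n_bins + 1)
    counts, _ = np.histogram(wrapped, bins=edges)
    span = counts.max() - counts.min()
    if span == 0:
        return edges, np.zeros(n_bins)
    return edges, (counts - counts.min()) / span


def reaching_time(traj: Trajectory, source, radius: float):
    """First sample time with |r_c - source| < radius, else ``CENSORED``.

    Censored trajectories report the final sample time alongside the
    marker: returns (time, reached_flag).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    source = np.asarray(source, dtype=float)
    d = np.linalg.norm(traj.r_c - source, axis=1)
    hit = np.nonzero(d < radius)[0]
    if hit.size:
        return float(traj.t[hit[0]]), True
    return float(traj.t[-1]), False


def circular_variance(angles) -> float:
    """1 - |mean resultant vector|; 0 for identical angles, ~1 for uniform."""
    angles = np.asarray(angles, dtype=float)
    return float(1.0 - np.hypot(np.cos(angles).mean(), np.sin(angles).mean()))


def write_modes_csv(path, times, labels) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["window_start_t", "mode"])
        for t, lab in zip(times, labels):
            w.writerow([f"{t:.6g}", lab])


def write_histogram_json(path, edges, intensities) -> None:
    with open(path, "w") as fh:
        json.dump({"bin_edges": list(map(float, edges)),
                   "intensities": list(map(float, intensities))}, fh, indent=2)
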