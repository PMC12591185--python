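"""Closed-form chemical concentration landscapes.

Every field is an analytic function C(x, y, t) on the continuous plane
(never rasterized).  The family covers the navigation scenarios:

* ``linear_radial`` -- the training landscape C = 1 - r/20, with constant
  radial gradient dC/dr = -0.05;
* ``gaussian`` -- isotropic normal bumps of width sigma;
* ``lognormal_skew`` -- a log-normal profile along x (steep on one side of
  the source, shallow on the other), defined for x > -8;
* ``multimodal`` -- a sum of Gaussian peaks with distinct heights;
* ``fluctuating`` -- a multimodal base whose peaks drift, stretch radially
  and (for the minor peaks) breathe in amplitude over time, all
  deterministically from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FieldDomainError",
    "ChemicalField",
    "make_linear_radial",
    "make_gaussian",
    "make_lognormal_skew",
    "make_multimodal",
    "make_fluctuating",
    "numeric_gradient",
    "field_from_spec",
    "get_field",
    "FIELD_REGISTRY",
]


class FieldDomainError(ValueError):
    """Evaluation outside the field's domain of definition."""


@dataclass(frozen=True)
class ChemicalField:
    """A scalar concentration field C(x, y, t).

    ``fn`` is vectorized over x and y.  ``source`` gives the location of
    the global concentration maximum at time t (the navigation target).
    ``time_dependent`` is False for static fields, whose values are
    identical for all t.
    """

    kind: str
    params: dict
    fn: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    source_fn: Callable[[float], np.ndarray]
    time_dependent: bool = False

    def __call__(self, x, y, t: float = 0.0):
        out = self.fn(np.asarray(x, dtype=float), np.asarray(y, dtype=float), float(t))
        if np.ndim(x) == 0 and np.ndim(y) == 0:
            return float(out)
        return out

    def source(self, t: float = 0.0) -> np.ndarray:
        return np.asarray(self.source_fn(float(t)), dtype=float)


def make_linear_radial(center: Sequence[float] = (0.0, 0.0)) -> ChemicalField:
    """Radially linear field C = 1 - r/20 about ``center`` (dC/dr = -0.05).

    The field goes negative for r > 20; no clipping is applied, since the
    navigator only ever consumes concentration differences.
    """
    cx, cy = float(center[0]), float(center[1])

    def fn(x, y, t):
        return 1.0 - np.sqrt((x - cx) ** 2 + (y - cy) ** 2) / 20.0

    return ChemicalField(
        kind="linear_radial", params={"center": (cx, cy)}, fn=fn,
        source_fn=lambda t: np.array([cx, cy]),
    )


def make_gaussian(sigma: float, center: Sequence[float] = (0.0, 0.0)) -> ChemicalField:
    """Isotropic Gaussian C = exp(-[(x-cx)^2 + (y-cy)^2] / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    cx, cy = float(center[0]), float(center[1])
    s2 = 2.0 * sigma**2

    def fn(x, y, t):
        return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / s2)

    return ChemicalField(
        kind="gaussian", params={"sigma": float(sigma), "center": (cx, cy)}, fn=fn,
        source_fn=lambda t: np.array([cx, cy]),
    )


def make_lognormal_skew(sigma: float = 1.0) -> ChemicalField:
    """Skewed field C = (5 / (pi sigma^2)) exp(-[ln(x+8)^2/sigma^2 + y^2/sigma^2]/2).

    Log-normal along x, Gaussian along y; defined only for x > -8.  The
    global maximum sits at (-7, 0), where ln(x + 8) = 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    amp = 5.0 / (math.pi * sigma**2)

    def fn(x, y, t):
        if np.any(x <= -8.0):
            raise FieldDomainError("lognormal_skew field is defined only for x > -8")
        return amp * np.exp(-0.5 * ((np.log(x + 8.0) / sigma) ** 2 + (y / sigma) ** 2))

    return ChemicalField(
        kind="lognormal_skew", params={"sigma": float(sigma)}, fn=fn,
        source_fn=lambda t: np.array([-7.0, 0.0]),
    )


def _check_peaks(peaks):
    peaks = [((float(c[0]), float(c[1])), float(s), float(a)) for c, s, a in peaks]
    if len(peaks) < 1:
        raise ValueError("at least one peak is required")
    if any(s <= 0 for _, s, _ in peaks):
        raise ValueError("peak widths must be positive")
    if any(a <= 0 for _, _, a in peaks):
        raise ValueError("peak amplitudes must be positive")
    return peaks


def make_multimodal(peaks: Sequence[tuple]) -> ChemicalField:
    """Sum of Gaussian peaks; ``peaks`` is a list of (center, sigma, amplitude).

    With at least two peaks separated by more than ~3x the largest width the
    field has multiple local maxima of different heights.
    """
    peaks = _check_peaks(peaks)
    if len(peaks) < 2:
        raise ValueError("a multimodal field needs at least two peaks")

    def fn(x, y, t):
        out = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
        for (cx, cy), s, a in peaks:
            out = out + a * np.exp(-0.5 * ((x - cx) ** 2 + (y - cy) ** 2) / s**2)
        return out

    dominant = max(peaks, key=lambda p: p[2])

    return ChemicalField(
        kind="multimodal", params={"peaks": peaks}, fn=fn,
        source_fn=lambda t: np.array(dominant[0]),
    )


def make_fluctuating(
    peaks: Sequence[tuple],
    drift_velocity: Sequence[float] = (0.0, 0.0),
    stretch_rate: float = 0.0,
    noise_seed: int = 0,
    noise_amplitude: float = 0.3,
    noise_period: float = 400.0,
) -> ChemicalField:
    """Time-varying multimodal field: drifting, radially stretching peaks.

    All peak centers translate at ``drift_velocity``; widths grow as
    sigma_k (1 + stretch_rate * t); minor-peak amplitudes are modulated by
    smooth seeded sinusoids so the landscape fluctuates without ever moving
    the global maximum away from the drifted dominant peak.  Evaluation is
    a pure function of (x, y, t, seed): identical across runs.
    """
    peaks = _check_peaks(peaks)
    vx, vy = float(drift_velocity[0]), float(drift_velocity[1])
    stretch = float(stretch_rate)
    rng = np.random.default_rng(noise_seed)
    dominant_idx = int(np.argmax([a for _, _, a in peaks]))
    phases = rng.uniform(0.0, 2.0 * math.pi, size=len(peaks))
    freqs = 2.0 * math.pi / (noise_period * rng.uniform(0.75, 1.5, size=len(peaks)))

    def fn(x, y, t):
        out = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
        grow = 1.0 + stretch * t
        if grow <= 0:
            raise FieldDomainError("stretch_rate drove a peak width nonpositive")
        for k, ((cx, cy), s, a) in enumerate(peaks):
            if k != dominant_idx and noise_amplitude > 0:
                a = a * (1.0 + noise_amplitude * math.sin(freqs[k] * t + phases[k]))
            st = s * grow
            out = out + a * np.exp(
                -0.5 * ((x - cx - vx * t) ** 2 + (y - cy - vy * t) ** 2) / st**2
            )
        return out

    c0 = np.array(peaks[dominant_idx][0])

    return ChemicalField(
        kind="fluctuating",
        params={
            "peaks": peaks, "drift_velocity": (vx, vy), "stretch_rate": stretch,
            "noise_seed": int(noise_seed), "noise_amplitude": float(noise_amplitude),
            "noise_period": float(noise_period),
        },
        fn=fn,
        source_fn=lambda t: c0 + np.array([vx, vy]) * t,
        time_dependent=True,
    )


def numeric_gradient(field: ChemicalField, x: float, y: float, t: float = 0.0,
                     h: float = 1e-5) -> np.ndarray:
    """Central-difference spatial gradient of C at (x, y, t); error O(h^2)."""
    if h <= 0:
        raise ValueError("h must be positive")
    gx = (field(x + h, y, t) - field(x - h, y, t)) / (2.0 * h)
    gy = (field(x, y + h, t) - field(x, y - h, t)) / (2.0 * h)
    return np.array([gx, gy])


# --------------------------------------------------------------------------
# named field registry
# --------------------------------------------------------------------------

DEFAULT_PEAKS = [((-5.0, 0.0), 2.0, 0.6), ((5.0, 0.0), 2.0, 1.0)]


def _registry() -> dict:
    reg = {
        "training": lambda: make_linear_radial((0.0, 0.0)),
        "shifted": lambda: make_linear_radial((1.0, 1.0)),
        "skewed": lambda: make_lognormal_skew(1.0),
        "multimodal": lambda: make_multimodal(DEFAULT_PEAKS),
        "fluctuating": lambda: make_fluctuating(
            DEFAULT_PEAKS, drift_velocity=(0.003, 0.002), stretch_rate=3e-4, noise_seed=7
        ),
    }
    for s in (2, 4, 6, 8, 10):
        reg[f"gaussian_s{s}"] = (lambda sig: (lambda: make_gaussian(sig)))(float(s))
    return reg


FIELD_REGISTRY = _registry()


def get_field(name: str) -> ChemicalField:
    """Resolve a named field from the registry."""
    try:
        return FIELD_REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown field {name!r}; known: {sorted(FIELD_REGISTRY)}"
        ) from None


def field_from_spec(spec: dict) -> ChemicalField:
    """Build a field from a config mapping ({'kind': ..., **params})."""
    spec = dict(spec)
    if "name" in spec:
        return get_field(spec["name"])
    kind = spec.pop("kind")
    builders = {
        "linear_radial": make_linear_radial,
        "gaussian": make_gaussian,
        "lognormal_skew": make_lognormal_skew,
        "multimodal": make_multimodal,
        "fluctuating": make_fluctuating,
    }
    if kind not in builders:
        raise KeyError(f"unknown field kind {kind!r}")
    return builders[kind](**spec)
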