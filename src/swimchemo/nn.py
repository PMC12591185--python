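"""Minimal dense neural networks with hand-written backprop.

Small fully-connected networks (the two-hidden-layer, 128-unit layout used
by both learners) in float32 numpy, with an Adam optimizer.  Forward passes
cache activations; ``backward`` returns parameter gradients and the
gradient with respect to the input (needed to differentiate a Q-network
with respect to its action input).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "HIDDEN_LAYOUT"]

HIDDEN_LAYOUT = (128, 128)


class MLP:
    """Fully-connected ReLU network with a linear output layer."""

    def __init__(self, in_dim: int, out_dim: int, hidden=HIDDEN_LAYOUT, rng=None):
        if tuple(hidden) != HIDDEN_LAYOUT:
            raise ValueError(f"hidden layout is fixed at {HIDDEN_LAYOUT}")
        rng = rng if rng is not None else np.random.default_rng(0)
        dims = [in_dim, *hidden, out_dim]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He-style init for the ReLU trunk
            scale = np.sqrt(2.0 / d_in)
            self.W.append((rng.standard_normal((d_in, d_out)) * scale).astype(np.float32))
            self.b.append(np.zeros(d_out, dtype=np.float32))
        self.in_dim = in_dim
        self.out_dim = out_dim

    # --- parameter plumbing ----------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.W, self.b):
            out.extend([w, b])
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        it = iter(params)
        for i in range(len(self.W)):
            self.W[i] = next(it).astype(np.float32).reshape(self.W[i].shape)
            self.b[i] = next(it).astype(np.float32).reshape(self.b[i].shape)

    def copy(self) -> "MLP":
        other = MLP.__new__(MLP)
        other.W = [w.copy() for w in self.W]
        other.b = [b.copy() for b in self.b]
        other.in_dim = self.in_dim
        other.out_dim = self.out_dim
        return other

    # --- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, need_cache: bool = False):
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 1
        h = x[None, :] if squeeze else x
        cache = [h]
        n = len(self.W)
        for i in range(n):
            h = h @ self.W[i] + self.b[i]
            if i < n - 1:
                h = np.maximum(h, 0.0)
            cache.append(h)
        out = h[0] if squeeze else h
        if need_cache:
            return out, cache
        return out

    def __call__(self, x):
        return self.forward(x)

    def backward(self, dout: np.ndarray, cache):
        """Backprop; returns (param grads aligned with parameters(), dx)."""
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        d = np.asarray(dout, dtype=np.float32)
        if d.ndim == 1:
            d = d[None, :]
        n = len(self.W)
        for i in range(n - 1, -1, -1):
            inp = cache[i]
            if i < n - 1:
                d = d * (cache[i + 1] > 0)  # ReLU mask
            grads_W[i] = inp.T @ d
            grads_b[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        grads = []
        for gw, gb in zip(grads_W, grads_b):
            grads.extend([gw, gb])
        return grads, d

    def input_gradient(self, dout: np.ndarray, cache):
        """Gradient with respect to the input only (skips parameter grads)."""
        d = np.asarray(dout, dtype=np.float32)
        if d.ndim == 1:
            d = d[None, :]
        n = len(self.W)
        for i in range(n - 1, -1, -1):
            if i < n - 1:
                d = d * (cache[i + 1] > 0)
            d = d @ self.W[i].T
        return d


class Adam:
    """Adam over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state(self) -> dict:
        return {"m": [a.copy() for a in self.m], "v": [a.copy() for a in self.v], "t": self.t}

    def load_state(self, state: dict) -> None:
        self.m = [np.asarray(a, dtype=np.float32).copy() for a in state["m"]]
        self.v = [np.asarray(a, dtype=np.float32).copy() for a in state["v"]]
        self.t = int(state["t"])
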