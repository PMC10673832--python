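"""Minimal recurrent network: one LSTM layer, a dense head producing a
categorical distribution over a fixed glucose grid, Adam, and full
backpropagation through time.  Implemented directly in numpy; everything is
deterministic given the seed.

The probabilistic head follows the model being reproduced: at each 15-min
step the network emits likelihoods over 100 candidate glucose values and is
trained by (negative) log-likelihood of the observed next glucose.  True
targets are encoded as a two-bin linear interpolation on the grid so the
distribution's expectation can resolve glucose below the grid spacing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def soft_targets(glucose: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Two-bin interpolation encoding of true glucose values on the grid."""
    g = np.asarray(glucose, dtype=float)
    lo, hi = grid[0], grid[-1]
    step = (hi - lo) / (grid.size - 1)
    pos = np.clip((g - lo) / step, 0.0, grid.size - 1.0)
    j = np.floor(pos).astype(int)
    j = np.minimum(j, grid.size - 2)
    frac = pos - j
    out = np.zeros(g.shape + (grid.size,))
    idx = np.indices(g.shape)
    out[(*idx, j)] = 1.0 - frac
    out[(*idx, j + 1)] += frac
    return out


@dataclass
class LstmParams:
    Wx: np.ndarray  # (F, 4H)
    Wh: np.ndarray  # (H, 4H)
    b: np.ndarray  # (4H,)
    Wy: np.ndarray  # (H, K)
    by: np.ndarray  # (K,)

    @property
    def hidden(self) -> int:
        return self.Wh.shape[0]

    def flat(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b, self.Wy, self.by]

    @staticmethod
    def init(n_features: int, hidden: int, n_out: int, rng: np.random.Generator):
        def w(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
        return LstmParams(
            Wx=w((n_features, 4 * hidden), n_features),
            Wh=w((hidden, 4 * hidden), hidden),
            b=b,
            Wy=w((hidden, n_out), hidden),
            by=np.zeros(n_out),
        )


class LstmCore:
    """Sequence-to-sequence LSTM with a softmax head at every step."""

    def __init__(self, params: LstmParams):
        self.p = params

    def step(self, x, h, c):
        """One LSTM step; returns (h, c, cache-for-backprop)."""
        p = self.p
        H = p.hidden
        z = x @ p.Wx + h @ p.Wh + p.b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        cache = (x, h, c, i, f, g, o, c_new)
        return h_new, c_new, cache

    def forward(
        self,
        X: np.ndarray,
        feedback_prob: float = 0.0,
        rng: np.random.Generator | None = None,
        glucose_channel: int = 0,
        grid_std: np.ndarray | None = None,
    ):
        """Run the network over X (B, T, F).

        With feedback_prob > 0 the glucose input channel at step t+1 is
        replaced, per sample with that probability, by the model's own step-t
        expectation on the standardized grid (scheduled sampling).  The
        fed-back value is treated as a constant in the backward pass.
        Returns (probs (B, T, K), caches).
        """
        B, T, F = X.shape
        H = self.p.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        probs = np.empty((B, T, self.p.by.size))
        x_prev_pred = None
        for t in range(T):
            x = X[:, t, :].copy()
            if x_prev_pred is not None and feedback_prob > 0.0 and rng is not None:
                use = rng.random(B) < feedback_prob
                x[use, glucose_channel] = x_prev_pred[use]
            h, c, cache = self.step(x, h, c)
            logits = h @ self.p.Wy + self.p.by
            pt = softmax(logits)
            probs[:, t, :] = pt
            caches.append((cache, pt))
            if grid_std is not None:
                x_prev_pred = pt @ grid_std  # expectation in standardized units
        return probs, caches

    def backward(self, caches, probs, targets):
        """Cross-entropy gradient through all steps; targets (B, T, K)."""
        p = self.p
        B, T, K = probs.shape
        H = p.hidden
        grads = LstmParams(
            Wx=np.zeros_like(p.Wx),
            Wh=np.zeros_like(p.Wh),
            b=np.zeros_like(p.b),
            Wy=np.zeros_like(p.Wy),
            by=np.zeros_like(p.by),
        )
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        scale = 1.0 / (B * T)
        for t in range(T - 1, -1, -1):
            (x, h_prev, c_prev, i, f, g, o, c_new), pt = caches[t]
            dlogits = (pt - targets[:, t, :]) * scale
            h_t = o * np.tanh(c_new)
            grads.Wy += h_t.T @ dlogits
            grads.by += dlogits.sum(axis=0)
            dh = dlogits @ p.Wy.T + dh_next
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads.Wx += x.T @ dz
            grads.Wh += h_prev.T @ dz
            grads.b += dz.sum(axis=0)
            dh_next = dz @ p.Wh.T
        return grads


class Adam:
    def __init__(self, params: LstmParams, lr: float = 0.01, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in params.flat()]
        self.v = [np.zeros_like(a) for a in params.flat()]
        self.t = 0

    def update(self, grads: LstmParams, clip: float = 5.0):
        self.t += 1
        gs = grads.flat()
        norm = np.sqrt(sum(float((g**2).sum()) for g in gs))
        if norm > clip:
            gs = [g * (clip / norm) for g in gs]
        for a, g, m, v in zip(self.params.flat(), gs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def nll(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean cross-entropy between soft targets and predicted distributions."""
    return float(-(targets * np.log(probs + 1e-12)).sum(axis=-1).mean())
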