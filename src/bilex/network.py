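"""Numpy building blocks for the pair classifier.

A deliberately small autodiff-free stack: a masked multi-timestep LSTM
layer with exact backpropagation-through-time, a sigmoid feed-forward
head, inverted dropout, and an Adam optimizer.  Shapes follow the
(batch, time, features) convention; masks are (batch, time) floats where 0
marks positions past a sequence's end (the state is held constant there,
so the hidden state at the last timestep equals the state at each
sequence's own final position).

Gate layout inside the fused weight matrices is [input, forget, cell,
output]; the forget-gate bias is initialised to 1.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class Adam:
    """Adaptive-moment gradient optimizer at standard default settings."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class LSTMLayer:
    """One LSTM layer over a padded, masked batch of sequences."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator,
                 init_scale: float = 0.08):
        self.d_in, self.d_hidden = d_in, d_hidden
        H = d_hidden
        self.Wx = rng.uniform(-init_scale, init_scale, (d_in, 4 * H))
        self.Wh = rng.uniform(-init_scale, init_scale, (H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # forget-gate bias

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray):
        """x: (B,T,d_in), mask: (B,T) -> h_seq (B,T,H), cache."""
        B, T, _ = x.shape
        H = self.d_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        h_seq = np.empty((B, T, H))
        steps = []
        for t in range(T):
            a = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t:t + 1]
            steps.append((x[:, t], h, c, i, f, g, o, tc, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
            h_seq[:, t] = h
        return h_seq, steps

    def backward(self, dh_seq: np.ndarray, cache):
        """dh_seq: (B,T,H) upstream gradient on h_seq.

        Returns (dx_seq, [dWx, dWh, db]).
        """
        B, T, H = dh_seq.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx_seq = np.empty((B, T, self.d_in))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc, m = cache[t]
            dh_total = dh_seq[:, t] + dh_next
            dc_total = dc_next
            dh_new = m * dh_total
            dc_new = m * dc_total + dh_new * o * (1 - tc * tc)
            da = np.concatenate(
                [
                    dc_new * g * i * (1 - i),
                    dc_new * c_prev * f * (1 - f),
                    dc_new * i * (1 - g * g),
                    dh_new * tc * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx_seq[:, t] = da @ self.Wx.T
            dh_next = (1 - m) * dh_total + da @ self.Wh.T
            dc_next = (1 - m) * dc_total + dc_new * f
        return dx_seq, [dWx, dWh, db]


class FeedForward:
    """H sigmoid hidden layers plus a sigmoid scalar output unit."""

    def __init__(self, d_in: int, hidden_layers: int, hidden_width: int | None,
                 rng: np.random.Generator, init_scale: float = 0.08):
        width = d_in if hidden_width is None else hidden_width
        self.Ws: list[np.ndarray] = []
        self.bs: list[np.ndarray] = []
        prev = d_in
        for _ in range(hidden_layers):
            self.Ws.append(rng.uniform(-init_scale, init_scale, (prev, width)))
            self.bs.append(np.zeros(width))
            prev = width
        self.Wo = rng.uniform(-init_scale, init_scale, (prev, 1))
        self.bo = np.zeros(1)

    def params(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.Ws, self.bs):
            out.extend([W, b])
        out.extend([self.Wo, self.bo])
        return out

    def forward(self, r0: np.ndarray):
        """r0: (B, d_in) -> scores (B,), cache of layer activations."""
        acts = [r0]
        h = r0
        for W, b in zip(self.Ws, self.bs):
            h = sigmoid(h @ W + b)
            acts.append(h)
        score = sigmoid(h @ self.Wo + self.bo)[:, 0]
        return score, acts

    def backward(self, dlogit: np.ndarray, cache):
        """dlogit: (B,) gradient w.r.t. the output pre-activation.

        Returns (dr0, grads aligned with params()).
        """
        acts = cache
        dl = dlogit[:, None]
        dWo = acts[-1].T @ dl
        dbo = dl.sum(axis=0)
        dh = dl @ self.Wo.T
        gW, gb = [], []
        for li in range(len(self.Ws) - 1, -1, -1):
            a = acts[li + 1]
            da = dh * a * (1 - a)
            gW.append(acts[li].T @ da)
            gb.append(da.sum(axis=0))
            dh = da @ self.Ws[li].T
        grads = []
        for W, b in zip(reversed(gW), reversed(gb)):
            grads.extend([W, b])
        grads.extend([dWo, dbo])
        return dh, grads


def dropout_mask(shape, keep_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier: E[mask * x] = x."""
    if keep_prob >= 1.0:
        return np.ones(shape)
    return (rng.random(shape) < keep_prob) / keep_prob


def binary_cross_entropy(scores: np.ndarray, labels: np.ndarray,
                         eps: float = 1e-7) -> float:
    """Summed cross-entropy loss; scores clamped away from {0,1} by eps."""
    s = np.clip(scores, eps, 1 - eps)
    y = np.asarray(labels, dtype=float)
    return float(np.sum(-y * np.log(s) - (1 - y) * np.log(1 - s)))
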