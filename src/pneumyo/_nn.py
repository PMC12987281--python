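"""Minimal numpy neural-network kernels for the pressure-window classifier.

Implements exactly the layers the classifier needs -- 1-D valid convolution,
max pooling, LSTM (gate order i, f, g, o; tanh/sigmoid activations, forget
bias initialized to 1), inverted dropout, dense softmax -- together with
analytic backpropagation and the Adam optimizer.  The layer conventions
(weight shapes, initializers) follow the common deep-learning defaults:
Glorot-uniform input kernels, orthogonal recurrent kernels, zero biases.

Gradient correctness is enforced in the test suite by central finite
differences on a down-sized network.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot_uniform",
    "orthogonal",
    "conv1d_forward",
    "conv1d_backward",
    "maxpool1d_forward",
    "maxpool1d_backward",
    "lstm_forward",
    "lstm_backward",
    "dense_forward",
    "softmax",
    "Adam",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix sign convention for determinism
    return q[:rows, :cols] if rows >= cols else q.T


# ---------------------------------------------------------------- conv / pool

def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 1-D convolution (cross-correlation). x: (B,T,C), W: (K,C,F)."""
    B, T, C = x.shape
    K, _, F = W.shape
    out_len = T - K + 1
    y = np.empty((B, out_len, F))
    y[:] = b
    for k in range(K):
        y += x[:, k : k + out_len, :] @ W[k]
    return y, (x, W)


def conv1d_backward(dy: np.ndarray, cache):
    x, W = cache
    K, C, F = W.shape
    out_len = dy.shape[1]
    dW = np.empty_like(W)
    dx = np.zeros_like(x)
    for k in range(K):
        xs = x[:, k : k + out_len, :]
        dW[k] = np.einsum("btc,btf->cf", xs, dy)
        dx[:, k : k + out_len, :] += dy @ W[k].T
    db = dy.sum(axis=(0, 1))
    return dx, dW, db


def maxpool1d_forward(x: np.ndarray, pool: int):
    """Non-overlapping max pool along time; trailing remainder is dropped."""
    B, T, C = x.shape
    out_len = T // pool
    xr = x[:, : out_len * pool, :].reshape(B, out_len, pool, C)
    idx = xr.argmax(axis=2)
    y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return y, (x.shape, pool, idx)


def maxpool1d_backward(dy: np.ndarray, cache):
    shape, pool, idx = cache
    B, T, C = shape
    out_len = dy.shape[1]
    dxr = np.zeros((B, out_len, pool, C))
    np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros(shape)
    dx[:, : out_len * pool, :] = dxr.reshape(B, out_len * pool, C)
    return dx


# ----------------------------------------------------------------------- lstm

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_forward(x: np.ndarray, W: np.ndarray, U: np.ndarray, b: np.ndarray):
    """LSTM over a full sequence. x: (B,T,C); W: (C,4H); U: (H,4H); b: (4H,).

    Gate order in the packed weight matrices is input, forget, cell
    candidate, output.  Returns the full hidden sequence (B,T,H).
    """
    B, T, C = x.shape
    H = U.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    caches = []
    for t in range(T):
        z = x[:, t, :] @ W + h @ U + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        hs[:, t, :] = h
        caches.append((x[:, t, :], h_prev, c_prev, i, f, g, o, tc))
    return hs, (caches, W, U, x.shape)


def lstm_backward(dhs: np.ndarray, cache):
    """Backprop through time. dhs: (B,T,H) gradient on every hidden output."""
    caches, W, U, x_shape = cache
    B, T, C = x_shape
    H = U.shape[0]
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * H)
    dx = np.empty((B, T, C))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        xt, h_prev, c_prev, i, f, g, o, tc = caches[t]
        dh = dhs[:, t, :] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc**2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f),
             dg * (1.0 - g**2), do * o * (1.0 - o)], axis=1)
        dW += xt.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t, :] = dz @ W.T
        dh_next = dz @ U.T
        dc_next = dc * f
    return dx, dW, dU, db


# ---------------------------------------------------------------- dense / sm

def dense_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ----------------------------------------------------------------------- adam

class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
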