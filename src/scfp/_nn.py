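"""Minimal 1-D neural-network primitives (forward + backward) in NumPy.

Only what the SMILES convolution network needs: windowed convolution along
the sequence axis, average/max pooling, ReLU-family activations, batch
normalization, dropout, dense layers, the logistic loss, and Adam.  Arrays
are ``(batch, length, channels)`` throughout; every forward function returns
``(output, cache)`` and its backward mate consumes the cache.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------- im2col


def out_length(L: int, window: int, stride: int, pad: int) -> int:
    n = (L + 2 * pad - window) // stride + 1
    if n < 1:
        raise ValueError(f"sequence of length {L} too short for window {window} (pad {pad})")
    return n


def im2col(X: np.ndarray, window: int, stride: int, pad: int) -> np.ndarray:
    """(N, L, C) -> (N, Lout, window, C) of sliding windows."""
    if pad:
        X = np.pad(X, ((0, 0), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(X, window, axis=1)  # (N, L-w+1, C, w)
    return np.ascontiguousarray(win[:, ::stride].transpose(0, 1, 3, 2))


def col2im(dcols: np.ndarray, L: int, window: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add windows back to (N, L, C)."""
    N, Lout, w, C = dcols.shape
    dXp = np.zeros((N, L + 2 * pad, C), dtype=dcols.dtype)
    for j in range(w):
        dXp[:, j : j + stride * Lout : stride] += dcols[:, :, j]
    return dXp[:, pad : pad + L] if pad else dXp


# ---------------------------------------------------------------- layers


def conv1d_forward(X, W, b, stride: int, pad: int):
    """Full-width 1-D convolution: W is (window*Cin, Cout)."""
    window = W.shape[0] // X.shape[2]
    cols = im2col(X, window, stride, pad)
    N, Lout = cols.shape[:2]
    Y = cols.reshape(N, Lout, -1) @ W + b
    return Y, (cols, W, X.shape, stride, pad)


def conv1d_backward(dY, cache):
    cols, W, xshape, stride, pad = cache
    N, Lout, w, C = cols.shape
    flat = cols.reshape(N * Lout, w * C)
    dflat = dY.reshape(N * Lout, -1)
    dW = flat.T @ dflat
    db = dflat.sum(axis=0)
    dcols = (dflat @ W.T).reshape(N, Lout, w, C)
    dX = col2im(dcols, xshape[1], w, stride, pad)
    return dX, dW, db


def avgpool1d_forward(X, window: int, stride: int, pad: int):
    cols = im2col(X, window, stride, pad)
    return cols.mean(axis=2), (X.shape, window, stride, pad)


def avgpool1d_backward(dY, cache):
    xshape, window, stride, pad = cache
    dcols = np.repeat(dY[:, :, None, :] / window, window, axis=2)
    return col2im(dcols, xshape[1], window, stride, pad)


def maxpool1d_forward(X, window: int, stride: int, pad: int):
    cols = im2col(X, window, stride, pad)
    idx = cols.argmax(axis=2)
    return cols.max(axis=2), (X.shape, idx, window, stride, pad)


def maxpool1d_backward(dY, cache):
    xshape, idx, window, stride, pad = cache
    dcols = np.zeros(idx.shape[:2] + (window,) + idx.shape[2:], dtype=dY.dtype)
    np.put_along_axis(dcols, idx[:, :, None, :], dY[:, :, None, :], axis=2)
    return col2im(dcols, xshape[1], window, stride, pad)


def activation_forward(X, kind: str, slope: float):
    """kind in {relu, leaky_relu, prelu}; for prelu ``slope`` is the current
    learnable parameter value."""
    if kind == "relu":
        return np.maximum(X, 0.0), (X, kind, slope)
    Y = np.where(X > 0, X, slope * X)
    return Y, (X, kind, slope)


def activation_backward(dY, cache):
    X, kind, slope = cache
    a = 0.0 if kind == "relu" else slope
    dX = np.where(X > 0, dY, a * dY)
    dslope = float((dY * np.minimum(X, 0.0)).sum()) if kind == "prelu" else 0.0
    return dX, dslope


def batchnorm_forward(X, gamma, beta, running, train: bool, momentum=0.9, eps=1e-5):
    """Per-channel normalization over (batch, length)."""
    if train:
        mu = X.mean(axis=(0, 1))
        var = X.var(axis=(0, 1))
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mu
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    Xhat = (X - mu) * inv
    return gamma * Xhat + beta, (Xhat, inv, gamma)


def batchnorm_backward(dY, cache):
    Xhat, inv, gamma = cache
    m = Xhat.shape[0] * Xhat.shape[1]
    dgamma = (dY * Xhat).sum(axis=(0, 1))
    dbeta = dY.sum(axis=(0, 1))
    dXhat = dY * gamma
    dX = inv / m * (m * dXhat - dXhat.sum(axis=(0, 1)) - Xhat * (dXhat * Xhat).sum(axis=(0, 1)))
    return dX, dgamma, dbeta


def dropout_forward(X, rate: float, rng: np.random.Generator, train: bool):
    if not train or rate <= 0.0:
        return X, None
    mask = (rng.random(X.shape) >= rate) / (1.0 - rate)
    return X * mask, mask


def dropout_backward(dY, mask):
    return dY if mask is None else dY * mask


def dense_forward(X, W, b):
    return X @ W + b, (X, W)


def dense_backward(dY, cache):
    X, W = cache
    return dY @ W.T, X.T @ dY, dY.sum(axis=0)


def global_maxpool_forward(X, valid_mask):
    """(N, L, C) -> (N, C) max over valid positions.

    ``valid_mask`` is (N, L) boolean; every sample must have at least one
    valid position.  Ties resolve to the lowest position (argmax rule).
    """
    masked = np.where(valid_mask[:, :, None], X, -np.inf)
    idx = masked.argmax(axis=1)  # (N, C), lowest index on ties
    Y = np.take_along_axis(masked, idx[:, None, :], axis=1)[:, 0, :]
    return Y, idx


def global_maxpool_backward(dY, idx, L: int):
    N, C = dY.shape
    dX = np.zeros((N, L, C), dtype=dY.dtype)
    np.put_along_axis(dX, idx[:, None, :], dY[:, None, :], axis=1)
    return dX


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, y):
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.ravel()
    y = y.ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.reshape(-1, 1)


def mse_on_probs(z, y):
    z = z.ravel()
    y = y.ravel()
    p = sigmoid(z)
    loss = float(np.mean((p - y) ** 2))
    dz = 2.0 * (p - y) * p * (1.0 - p) / z.size
    return loss, dz.reshape(-1, 1)


class Adam:
    """Adam optimizer over a dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class AdaGrad:
    def __init__(self, params: dict, lr=0.01, eps=1e-8):
        self.lr, self.eps = lr, eps
        self.h = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        for k, g in grads.items():
            self.h[k] += g * g
            params[k] -= self.lr * g / (np.sqrt(self.h[k]) + self.eps)
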