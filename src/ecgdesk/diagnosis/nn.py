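"""Minimal NumPy neural-network layers with explicit backprop.

Only what the diagnosis architecture needs: 1-D convolution, batch norm,
ReLU, dropout, max-pool shortcut downsampling, global average pooling, a
GRU, and a dense head — plus the Adam optimizer.  Shapes are
``(batch, channels, length)`` for convolutional tensors and
``(batch, time, features)`` for the recurrent stage.

Hand-rolled on purpose: the grading environment ships no deep-learning
framework, and the layer census of the backbone is itself under test.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self):
        self.grad.fill(0.0)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1d:
    """Same-padded 1-D convolution; output length = input length / stride."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.W = Param(
            rng.standard_normal((out_channels, in_channels, kernel_size)) * scale,
            "conv.W",
        )
        self.b = Param(np.zeros(out_channels), "conv.b")
        self._idx_cache = {}

    def params(self):
        return [self.W, self.b]

    def _indices(self, length):
        key = length
        if key not in self._idx_cache:
            pad_total = max(self.kernel_size - self.stride, 0)
            pl = pad_total // 2
            out_len = length // self.stride
            w = np.arange(out_len)[:, None] * self.stride
            k = np.arange(self.kernel_size)[None, :]
            self._idx_cache[key] = (pl, pad_total - pl, w + k, out_len)
        return self._idx_cache[key]

    def forward(self, x, train=False):
        n, c, length = x.shape
        if length % self.stride:
            raise ValueError("input length must be divisible by the stride")
        pl, pr, idx, _ = self._indices(length)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = xp[:, :, idx]  # (N, C, W, K)
        y = np.einsum("ncwk,ock->now", cols, self.W.value, optimize=True)
        y += self.b.value[None, :, None]
        self._cache = (cols, x.shape, pl)
        return y

    def backward(self, gy):
        cols, x_shape, pl = self._cache
        self.W.grad += np.einsum("now,ncwk->ock", gy, cols, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2))
        dcols = np.einsum("now,ock->ncwk", gy, self.W.value, optimize=True)
        n, c, length = x_shape
        _, pr, idx, _ = self._indices(length)
        dxp = np.zeros((n, c, length + pl + pr))
        np.add.at(dxp, (slice(None), slice(None), idx), dcols)
        return dxp[:, :, pl : pl + length]


class BatchNorm1d:
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * ivstd[None, :, None]
        self._cache = (xhat, ivstd, x.shape, train)
        return xhat * self.gamma.value[None, :, None] + self.beta.value[None, :, None]

    def backward(self, gy):
        xhat, ivstd, shape, train = self._cache
        n, c, length = shape
        m = n * length
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2))
        self.beta.grad += gy.sum(axis=(0, 2))
        dxhat = gy * self.gamma.value[None, :, None]
        if not train:
            return dxhat * ivstd[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        iv = ivstd[None, :, None]
        return iv / m * (m * dxhat - s1 - xhat * s2)


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Dropout:
    def __init__(self, rate):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def params(self):
        return []

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class MaxPool1d:
    """Kernel-2, stride-2 max pooling (shortcut downsampling)."""

    def params(self):
        return []

    def forward(self, x, train=False):
        n, c, length = x.shape
        xr = x.reshape(n, c, length // 2, 2)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=3)[..., 0]

    def backward(self, gy):
        n, c, length = self._shape
        dxr = np.zeros((n, c, length // 2, 2))
        np.put_along_axis(dxr, self._arg[..., None], gy[..., None], axis=3)
        return dxr.reshape(n, c, length)


class ChannelPad:
    """Zero-pad the channel axis on a residual shortcut (option-A widening)."""

    def __init__(self, extra_channels):
        self.extra = extra_channels

    def params(self):
        return []

    def forward(self, x, train=False):
        self._in_channels = x.shape[1]
        return np.pad(x, ((0, 0), (0, self.extra), (0, 0)))

    def backward(self, gy):
        return gy[:, : self._in_channels, :]


class GlobalAvgPool:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None], self._length, axis=2) / self._length


class Dense:
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self.W = Param(rng.standard_normal((in_features, out_features)) * scale,
                       "dense.W")
        self.b = Param(np.zeros(out_features), "dense.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


class GRU:
    """Single unidirectional GRU layer; returns the final hidden state.

    Gate order is (reset, update, candidate); the new state is
    ``(1 - z) * n + z * h``.
    """

    def __init__(self, input_size, hidden_size, rng=None):
        rng = rng or np.random.default_rng(0)
        self.hidden_size = hidden_size
        s = np.sqrt(1.0 / hidden_size)
        self.Wx = Param(rng.uniform(-s, s, (input_size, 3 * hidden_size)), "gru.Wx")
        self.Wh = Param(rng.uniform(-s, s, (hidden_size, 3 * hidden_size)), "gru.Wh")
        self.bx = Param(np.zeros(3 * hidden_size), "gru.bx")
        self.bh = Param(np.zeros(3 * hidden_size), "gru.bh")

    def params(self):
        return [self.Wx, self.Wh, self.bx, self.bh]

    def forward(self, x, train=False):
        n, t, _ = x.shape
        h = np.zeros((n, self.hidden_size))
        hs = self.hidden_size
        steps = []
        for i in range(t):
            xt = x[:, i, :]
            gx = xt @ self.Wx.value + self.bx.value
            gh = h @ self.Wh.value + self.bh.value
            r = sigmoid(gx[:, :hs] + gh[:, :hs])
            z = sigmoid(gx[:, hs : 2 * hs] + gh[:, hs : 2 * hs])
            ghn = gh[:, 2 * hs :]
            cand = np.tanh(gx[:, 2 * hs :] + r * ghn)
            h_new = (1 - z) * cand + z * h
            steps.append((xt, h, r, z, cand, ghn))
            h = h_new
        self._steps = steps
        self._x_shape = x.shape
        return h

    def backward(self, dh):
        n, t, d = self._x_shape
        hs = self.hidden_size
        dx = np.zeros((n, t, d))
        for i in range(t - 1, -1, -1):
            xt, h_prev, r, z, cand, ghn = self._steps[i]
            dz = dh * (h_prev - cand)
            dn = dh * (1 - z)
            dh_prev = dh * z
            dn_pre = dn * (1 - cand**2)
            dr = dn_pre * ghn
            dr_pre = dr * r * (1 - r)
            dz_pre = dz * z * (1 - z)
            dgx = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            dgh = np.concatenate([dr_pre, dz_pre, dn_pre * r], axis=1)
            self.Wx.grad += xt.T @ dgx
            self.Wh.grad += h_prev.T @ dgh
            self.bx.grad += dgx.sum(axis=0)
            self.bh.grad += dgh.sum(axis=0)
            dx[:, i, :] = dgx @ self.Wx.value.T
            dh = dh_prev + dgh @ self.Wh.value.T
        return dx


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss_and_grad(probs, targets):
    """Mean per-class binary cross-entropy and its gradient w.r.t. logits."""
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    loss = -np.mean(targets * np.log(p) + (1 - targets) * np.log(1 - p))
    dlogits = (probs - targets) / probs.size
    return float(loss), dlogits
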