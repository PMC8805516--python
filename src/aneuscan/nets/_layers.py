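"""Minimal trainable layer library on numpy arrays.

Implements exactly what the candidate classifiers need — N-dimensional
convolution (2D and 3D), ReLU, squeeze-and-excitation channel gating,
residual blocks, global average pooling, dense layers, dropout, a
binary-cross-entropy-with-logits loss and an Adam optimizer — with
hand-written reverse-mode gradients.  Convolutions are evaluated by
looping over the k^d kernel offsets and accumulating strided-slice
einsums, which keeps memory flat and is fast for the small channel counts
used here.  Everything is deterministic given the seeds handed in.

Array layout is channels-first with an explicit batch axis:
``(B, C, *spatial)`` with 2 or 3 spatial dims.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param", "Layer", "Conv", "ReLU", "Dense", "SEGate", "ResBlock",
    "GlobalAvgPool", "Dropout", "Sequential", "Adam",
    "sigmoid", "bce_with_logits",
]


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits, targets, weights=None):
    """Stable weighted binary cross-entropy.

    Returns ``(loss, dloss_dlogits)`` with the loss averaged by total
    weight, so class weighting does not change the loss scale.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=np.float64)
    # softplus(z) - y*z, computed stably
    per = np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))
    total_w = w.sum()
    loss = float((w * per).sum() / total_w)
    grad = w * (sigmoid(z) - y) / total_w
    return loss, grad


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv(Layer):
    """k^d convolution (same padding) with optional stride, He-initialized.

    Evaluated as a single GEMM over an im2col patch matrix (float32), which
    is where essentially all training time goes; the input gradient is
    scattered back with k^d cheap strided slice-adds.
    """

    def __init__(self, in_channels, out_channels, ndim, kernel=3, stride=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.ndim, self.kernel, self.stride = int(ndim), int(kernel), int(stride)
        self.pad = self.kernel // 2
        fan_in = in_channels * kernel**ndim
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(out_channels, in_channels) + (kernel,) * ndim))
        self.b = Param(np.zeros(out_channels))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _out_shape(self, sp):
        return tuple((n + 2 * self.pad - self.kernel) // self.stride + 1 for n in sp)

    def _im2col(self, xp, out_sp):
        """(B*prod(out_sp), C*k^d) patch matrix from the padded input."""
        B, C = xp.shape[:2]
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (self.kernel,) * self.ndim, axis=tuple(range(2, 2 + self.ndim))
        )  # (B, C, *full_out, *k)
        if self.stride != 1:
            sl = (slice(None), slice(None)) + tuple(
                slice(None, None, self.stride) for _ in range(self.ndim)
            )
            win = win[sl]
        # -> (B, *out_sp, C, *k) contiguous, then flatten
        win = np.moveaxis(win, 1, 1 + self.ndim)
        return np.ascontiguousarray(win).reshape(
            B * int(np.prod(out_sp)), C * self.kernel**self.ndim
        )

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=np.float32)
        B, C = x.shape[:2]
        out_sp = self._out_shape(x.shape[2:])
        pad_width = [(0, 0), (0, 0)] + [(self.pad, self.pad)] * self.ndim
        xp = np.pad(x, pad_width)
        col = self._im2col(xp, out_sp)
        O = self.w.value.shape[0]
        w_mat = self.w.value.reshape(O, -1).astype(np.float32)
        out = col @ w_mat.T + self.b.value.astype(np.float32)
        out = np.moveaxis(out.reshape((B,) + out_sp + (O,)), -1, 1)
        self._cache = (col, xp.shape, x.shape, out_sp)
        return out

    def backward(self, dy):
        col, xp_shape, x_shape, out_sp = self._cache
        B, O = dy.shape[:2]
        dy_mat = np.ascontiguousarray(np.moveaxis(dy, 1, -1)).reshape(-1, O) \
            .astype(np.float32)
        self.b.grad += dy_mat.sum(axis=0)
        self.w.grad += (dy_mat.T @ col).reshape(self.w.value.shape)
        w_mat = self.w.value.reshape(O, -1).astype(np.float32)
        dcol = (dy_mat @ w_mat).reshape((B,) + out_sp + self.w.value.shape[1:])
        dcol = np.moveaxis(dcol, 1 + self.ndim, 1)  # (B, C, *out_sp, *k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for off in product(range(self.kernel), repeat=self.ndim):
            sl = tuple(slice(o, o + self.stride * n, self.stride)
                       for o, n in zip(off, out_sp))
            dxp[(slice(None), slice(None)) + sl] += \
                dcol[(slice(None), slice(None)) + (slice(None),) * self.ndim + off]
        unpad = (slice(None), slice(None)) + tuple(
            slice(self.pad, self.pad + n) for n in x_shape[2:]
        )
        return dxp[unpad]


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / in_features),
                                  size=(out_features, in_features)))
        self.b = Param(np.zeros(out_features))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class SEGate(Layer):
    """Squeeze-and-excitation: global average pool -> bottleneck MLP ->
    sigmoid channel weights -> channel-wise rescale."""

    def __init__(self, channels, reduction, rng=None):
        if channels % reduction:
            raise ValueError(f"se_reduction {reduction} must divide channel width {channels}")
        self.fc1 = Dense(channels, channels // reduction, rng)
        self.fc2 = Dense(channels // reduction, channels, rng)
        self.relu = ReLU()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x, train: bool = False):
        spatial = tuple(range(2, x.ndim))
        z = x.mean(axis=spatial)
        g = sigmoid(self.fc2.forward(self.relu.forward(self.fc1.forward(z))))
        self._cache = (x, g, spatial, x.shape)
        shape = g.shape + (1,) * len(spatial)
        return x * g.reshape(shape)

    def backward(self, dy):
        x, g, spatial, shape = self._cache
        n_spatial = int(np.prod(shape[2:]))
        g_b = g.reshape(g.shape + (1,) * len(spatial))
        dx = dy * g_b
        dg = (dy * x).sum(axis=spatial)
        ds = dg * g * (1.0 - g)  # through the sigmoid
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(ds)))
        dx += dz.reshape(dz.shape + (1,) * len(spatial)) / n_spatial
        return dx


class ResBlock(Layer):
    """conv-relu-conv with SE gating and a (projected) identity shortcut."""

    def __init__(self, in_channels, out_channels, ndim, se_reduction, stride=1, rng=None):
        self.conv1 = Conv(in_channels, out_channels, ndim, 3, stride, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv(out_channels, out_channels, ndim, 3, 1, rng)
        self.se = SEGate(out_channels, se_reduction, rng)
        self.proj = None
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv(in_channels, out_channels, ndim, 1, stride, rng)
        self.relu_out = ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params() + self.se.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train: bool = False):
        y = self.se.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))
        shortcut = x if self.proj is None else self.proj.forward(x)
        return self.relu_out.forward(y + shortcut)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dx_main = self.conv1.backward(self.relu1.backward(
            self.conv2.backward(self.se.backward(d))))
        dx_short = d if self.proj is None else self.proj.backward(d)
        return dx_main + dx_short


class GlobalAvgPool(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy):
        shape = self._shape
        n = int(np.prod(shape[2:]))
        return np.broadcast_to(
            dy.reshape(dy.shape + (1,) * (len(shape) - 2)), shape
        ) / n


class Dropout(Layer):
    """Inverted dropout on feature vectors; identity at eval time."""

    def __init__(self, rate, rng=None):
        self.rate = float(rate)
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train: bool = False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
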