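"""Convolution, normalization, pooling and linear layers (NumPy, CPU).

Convolutions run as im2col + BLAS matmul; the backward scatter iterates over
kernel offsets only, so it stays vectorized over batch and space.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import DTYPE, Module, Parameter, record_flops


def _tuple(v, n: int) -> tuple:
    if isinstance(v, (tuple, list)):
        if len(v) != n:
            raise ValueError(f"expected length-{n} tuple, got {v!r}")
        return tuple(int(x) for x in v)
    return (int(v),) * n


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class _ConvNd(Module):
    """Shared N-dimensional convolution machinery (N = 2 or 3 spatial dims)."""

    def __init__(self, ndim, in_ch, out_ch, kernel, stride, padding, bias, rng):
        self.ndim = ndim
        self.in_ch = int(in_ch)
        self.out_ch = int(out_ch)
        self.kernel = _tuple(kernel, ndim)
        self.stride = _tuple(stride, ndim)
        self.padding = _tuple(padding, ndim)
        if rng is None:
            rng = np.random.default_rng(0)
        fan_in = self.in_ch * int(np.prod(self.kernel))
        self.weight = Parameter(
            kaiming_normal(rng, (self.out_ch, self.in_ch) + self.kernel, fan_in)
        )
        self.bias = Parameter(np.zeros(self.out_ch)) if bias else None
        self._cache = None

    def _out_shape(self, spatial):
        return tuple(
            (s + 2 * p - k) // st + 1
            for s, k, st, p in zip(spatial, self.kernel, self.stride, self.padding)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.ndim != self.ndim + 2 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected input of shape (B, {self.in_ch}, {'x'.join('*' * self.ndim)}), "
                f"got {x.shape}"
            )
        spatial = x.shape[2:]
        out_spatial = self._out_shape(spatial)
        if any(o <= 0 for o in out_spatial):
            raise ValueError(f"kernel {self.kernel} too large for input {spatial}")
        pad = ((0, 0), (0, 0)) + tuple((p, p) for p in self.padding)
        xp = np.pad(x, pad) if any(self.padding) else x
        win = sliding_window_view(xp, self.kernel, axis=tuple(range(2, 2 + self.ndim)))
        slicer = (slice(None), slice(None)) + tuple(
            slice(0, None, s) for s in self.stride
        )
        win = win[slicer]
        # win: (B, Cin, *out_spatial, *kernel) -> cols (B, L, Cin*prod(k))
        B = x.shape[0]
        L = int(np.prod(out_spatial))
        axes = (0,) + tuple(range(2, 2 + self.ndim)) + (1,) + tuple(
            range(2 + self.ndim, 2 + 2 * self.ndim)
        )
        cols = np.ascontiguousarray(win.transpose(axes)).reshape(B, L, -1)
        w_mat = self.weight.data.reshape(self.out_ch, -1)
        out = cols @ w_mat.T
        if self.bias is not None:
            out += self.bias.data
        record_flops(
            macs=B * L * self.out_ch * w_mat.shape[1],
            adds=B * L * self.out_ch if self.bias is not None else 0,
        )
        if self.training:
            self._cache = (x.shape, out_spatial, cols)
        out = np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(
            (B, self.out_ch) + out_spatial
        )
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward (training mode)")
        x_shape, out_spatial, cols = self._cache
        B = x_shape[0]
        L = int(np.prod(out_spatial))
        g = np.ascontiguousarray(grad_out, dtype=DTYPE).reshape(B, self.out_ch, L)
        g = g.transpose(0, 2, 1)  # (B, L, out_ch)
        w_mat = self.weight.data.reshape(self.out_ch, -1)
        g2 = g.reshape(-1, self.out_ch)
        self.weight.grad += (
            g2.T @ cols.reshape(g2.shape[0], -1)
        ).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 1))
        gcols = (g @ w_mat).reshape((B,) + out_spatial + (self.in_ch,) + self.kernel)
        # move channel axis next to batch: (B, Cin, *out_spatial, *kernel)
        perm = (0, 1 + self.ndim) + tuple(range(1, 1 + self.ndim)) + tuple(
            range(2 + self.ndim, 2 + 2 * self.ndim)
        )
        gcols = gcols.transpose(perm)
        padded_spatial = tuple(
            s + 2 * p for s, p in zip(x_shape[2:], self.padding)
        )
        gxp = np.zeros((B, self.in_ch) + padded_spatial, dtype=DTYPE)
        for offset in np.ndindex(*self.kernel):
            slc = (slice(None), slice(None)) + tuple(
                slice(o, o + st * n, st)
                for o, st, n in zip(offset, self.stride, out_spatial)
            )
            gxp[slc] += gcols[(Ellipsis,) + offset]
        unpad = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for p, s in zip(self.padding, x_shape[2:])
        )
        return gxp[unpad]


class Conv2d(_ConvNd):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True, rng=None):
        super().__init__(2, in_ch, out_ch, kernel, stride, padding, bias, rng)


class Conv3d(_ConvNd):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True, rng=None):
        super().__init__(3, in_ch, out_ch, kernel, stride, padding, bias, rng)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_features = int(in_features)
        self.out_features = int(out_features)
        self.weight = Parameter(
            kaiming_normal(rng, (out_features, in_features), in_features)
        )
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"expected last dim {self.in_features}, got input shape {x.shape}"
            )
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        n_rows = int(np.prod(x.shape[:-1]))
        record_flops(
            macs=n_rows * self.in_features * self.out_features,
            adds=n_rows * self.out_features if self.bias is not None else 0,
        )
        if self.training:
            self._cache = x
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._cache
        g2 = grad_out.reshape(-1, self.out_features)
        x2 = x.reshape(-1, self.in_features)
        self.weight.grad += g2.T @ x2
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        return (g2 @ self.weight.data).reshape(x.shape)


class ReLU(Module):
    def forward(self, x):
        out = np.maximum(x, 0)
        if self.training:
            self._mask = x > 0
        return out

    def backward(self, grad_out):
        return grad_out * self._mask


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class GroupNorm(Module):
    """Group normalization over (channels-per-group x spatial) per sample.

    ``groups == channels`` gives instance normalization; ``groups == 1``
    normalizes the whole feature map jointly, preserving relative channel
    energies.
    """

    def __init__(self, channels, groups, eps=1e-5):
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.channels = int(channels)
        self.groups = int(groups)
        self.eps = float(eps)
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x):
        x = np.asarray(x, dtype=DTYPE)
        B, C = x.shape[:2]
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        spatial = x.shape[2:]
        xg = x.reshape(B, self.groups, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(x.shape)
        shape = (1, C) + (1,) * len(spatial)
        out = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        if self.training:
            self._cache = (xhat, inv)
        return out

    def backward(self, grad_out):
        xhat, inv = self._cache
        B, C = xhat.shape[:2]
        spatial = xhat.shape[2:]
        shape = (1, C) + (1,) * len(spatial)
        reduce_axes = (0,) + tuple(range(2, 2 + len(spatial)))
        self.gamma.grad += (grad_out * xhat).sum(axis=reduce_axes)
        self.beta.grad += grad_out.sum(axis=reduce_axes)
        dxh = (grad_out * self.gamma.data.reshape(shape)).reshape(B, self.groups, -1)
        xh = xhat.reshape(B, self.groups, -1)
        m1 = dxh.mean(axis=2, keepdims=True)
        m2 = (dxh * xh).mean(axis=2, keepdims=True)
        dx = inv * (dxh - m1 - xh * m2)
        return dx.reshape(xhat.shape)


class InstanceNorm(GroupNorm):
    def __init__(self, channels, eps=1e-5):
        super().__init__(channels, groups=channels, eps=eps)


class BatchNorm(Module):
    """Batch normalization per channel with running statistics."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        self.channels = int(channels)
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x):
        x = np.asarray(x, dtype=DTYPE)
        C = x.shape[1]
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, C) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        out = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        if self.training:
            self._cache = (xhat, inv, axes, shape)
        return out

    def backward(self, grad_out):
        xhat, inv, axes, shape = self._cache
        n = xhat.size // xhat.shape[1]
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        dxh = grad_out * self.gamma.data.reshape(shape)
        m1 = dxh.sum(axis=axes, keepdims=True) / n
        m2 = (dxh * xhat).sum(axis=axes, keepdims=True) / n
        return inv.reshape(shape) * (dxh - m1 - xhat * m2)


def make_norm(kind: str, channels: int) -> Module:
    if kind == "instance":
        return InstanceNorm(channels)
    if kind == "group":
        return GroupNorm(channels, groups=1)
    if kind == "batch":
        return BatchNorm(channels)
    raise ValueError(f"unknown norm kind {kind!r}; expected instance|group|batch")


def _pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic averaging matrix for adaptive pooling along one axis."""
    if n_out > n_in:
        raise ValueError(f"adaptive pool output {n_out} exceeds input {n_in}")
    A = np.zeros((n_out, n_in), dtype=DTYPE)
    for i in range(n_out):
        start = (i * n_in) // n_out
        end = -((-(i + 1) * n_in) // n_out)  # ceil
        A[i, start:end] = 1.0 / (end - start)
    return A


class AdaptiveAvgPool(Module):
    """Adaptive average pooling to a fixed output size, any spatial rank.

    Implemented as a separable chain of per-axis averaging matrices, so both
    the divisible and the ragged case are exact window means.
    """

    def __init__(self, out_size):
        self.out_size = tuple(int(s) for s in out_size)

    def forward(self, x):
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != len(self.out_size) + 2:
            raise ValueError(
                f"expected rank {len(self.out_size) + 2} input, got shape {x.shape}"
            )
        mats = [
            _pool_matrix(x.shape[2 + d], n_out)
            for d, n_out in enumerate(self.out_size)
        ]
        for d, A in enumerate(mats):
            x = np.moveaxis(np.tensordot(A, x, axes=(1, 2 + d)), 0, 2 + d)
        if self.training:
            self._mats = mats
        return np.ascontiguousarray(x)

    def backward(self, grad_out):
        g = grad_out
        for d, A in enumerate(self._mats):
            g = np.moveaxis(np.tensordot(A.T, g, axes=(1, 2 + d)), 0, 2 + d)
        return np.ascontiguousarray(g)
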