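"""Neural-network building blocks on top of the autograd engine.

All feature maps are ``(B, C, H, W)`` float64 tensors. Layers draw their
initial weights from an explicit ``numpy.random.Generator`` so that model
construction is fully seeded.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "GroupNorm",
    "downsample2x",
    "upsample2x",
]


class Module:
    """Lightweight module base: parameter discovery follows attribute order,
    giving deterministic parameter names for checkpoints."""

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}" if prefix == "" else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        mine = dict(self.named_parameters())
        if set(mine) != set(state):
            missing = set(mine) - set(state)
            extra = set(state) - set(mine)
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in mine.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(in_features)
        self.weight = Tensor(rng.normal(0.0, 1.0, (in_features, out_features)) * scale, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """k x k, stride 1, same-padding convolution via im2col + matmul."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3, zero_init: bool = False):
        fan_in = in_ch * kernel * kernel
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.weight = Tensor(rng.normal(0.0, 1.0, (fan_in, out_ch)) * scale, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        pad = k // 2
        B, C, H, W = x.shape
        w, b = self.weight, self.bias
        out_ch = w.shape[1]

        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        # (B, C, H, W, k, k) -> (B*H*W, C*k*k)
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)
        y = cols @ w.data + b.data
        y = y.reshape(B, H, W, out_ch).transpose(0, 3, 1, 2)

        def backward(g):
            g2 = g.transpose(0, 2, 3, 1).reshape(B * H * W, out_ch)
            if w.requires_grad:
                w._accum(cols.T @ g2)
            if b.requires_grad:
                b._accum(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ w.data.T).reshape(B, H, W, C, k, k)
                gxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
                for di in range(k):
                    for dj in range(k):
                        gxp[:, :, di : di + H, dj : dj + W] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                x._accum(gxp[:, :, pad : pad + H, pad : pad + W])

        return Tensor._make(y, (x, w, b), backward)


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups != 0:
            raise ValueError(f"groups {num_groups} must divide channels {num_channels}")
        self.num_groups = num_groups
        self.eps = eps
        self.weight = Tensor(np.ones(num_channels), requires_grad=True)
        self.bias = Tensor(np.zeros(num_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        # fused primitive: normalization statistics and the analytic backward
        # are computed in one pass (this layer dominates the graph otherwise)
        B, C, H, W = x.shape
        G = self.num_groups
        w, b = self.weight, self.bias
        xd = x.data.reshape(B, G, -1)
        mu = xd.mean(axis=2, keepdims=True)
        xc = xd - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = (xc * inv).reshape(B, C, H, W)
        out_data = y * w.data.reshape(1, C, 1, 1) + b.data.reshape(1, C, 1, 1)

        def backward(g):
            if w.requires_grad:
                w._accum((g * y).sum(axis=(0, 2, 3)))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gy = (g * w.data.reshape(1, C, 1, 1)).reshape(B, G, -1)
                yg = y.reshape(B, G, -1)
                m1 = gy.mean(axis=2, keepdims=True)
                m2 = (gy * yg).mean(axis=2, keepdims=True)
                gx = inv * (gy - m1 - yg * m2)
                x._accum(gx.reshape(B, C, H, W))

        return Tensor._make(out_data, (x, w, b), backward)


def _down_matrix(n: int) -> np.ndarray:
    # bilinear shrink by 2 == 2-tap average
    m = np.zeros((n // 2, n))
    for i in range(n // 2):
        m[i, 2 * i] = 0.5
        m[i, 2 * i + 1] = 0.5
    return m


def _up_matrix(n: int) -> np.ndarray:
    # bilinear enlarge by 2 (half-pixel centres, edges clamped)
    m = np.zeros((2 * n, n))
    for i in range(n):
        m[2 * i, i] += 0.75
        m[2 * i, max(i - 1, 0)] += 0.25
        m[2 * i + 1, i] += 0.75
        m[2 * i + 1, min(i + 1, n - 1)] += 0.25
    return m


_op_cache: dict = {}


def _cached(kind: str, n: int, dtype) -> np.ndarray:
    key = (kind, n, np.dtype(dtype).name)
    if key not in _op_cache:
        m = _down_matrix(n) if kind == "down" else _up_matrix(n)
        _op_cache[key] = m.astype(dtype)
    return _op_cache[key]


def downsample2x(x: Tensor) -> Tensor:
    """Halve H and W by separable bilinear interpolation."""
    B, C, H, W = x.shape
    dh = Tensor(_cached("down", H, x.data.dtype))
    dw = Tensor(_cached("down", W, x.data.dtype))
    return dh @ x @ dw.transpose(1, 0)


def upsample2x(x: Tensor) -> Tensor:
    """Double H and W by separable bilinear interpolation."""
    B, C, H, W = x.shape
    uh = Tensor(_cached("up", H, x.data.dtype))
    uw = Tensor(_cached("up", W, x.data.dtype))
    return uh @ x @ uw.transpose(1, 0)
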