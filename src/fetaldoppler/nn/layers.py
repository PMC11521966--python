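"""Layers with explicit forward/backward passes.

Activations are float32 arrays in NHWC layout (batch, height, width,
channels) — the cache-friendly layout for CPU numpy, since convolutions
reduce over the trailing channel axis with plain matmul.  Each layer caches
what its backward pass needs during ``forward(train=True)`` and releases it
after ``backward``.  Convolutions are stride-1 with 'same' zero padding;
spatial downsampling is done by 2x2 max-pooling and upsampling by
nearest-neighbour repetition.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: recursive parameter collection."""

    def params(self) -> list[Param]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """kxk stride-1 'same' convolution, computed as k*k shifted matmuls.

    The weight is stored as (k, k, C_in, C_out); for each kernel offset the
    padded input slice is multiplied by the (C_in, C_out) sub-matrix and
    accumulated, which avoids materializing im2col columns.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        rng: np.random.Generator | None = None,
        pad_mode: str = "reflect",
    ):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        if pad_mode not in ("reflect", "zeros"):
            raise ValueError("pad_mode must be 'reflect' or 'zeros'")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad_mode = pad_mode
        self.w = Param(he_init(rng, (k, k, c_in, c_out), c_in * k * k))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._xp = None

    def forward(self, x, train: bool = False):
        N, H, W, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        k, p = self.k, self.k // 2
        if p:
            mode = "reflect" if self.pad_mode == "reflect" else "constant"
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode=mode)
        else:
            xp = np.ascontiguousarray(x)
        y = np.empty((N, H, W, self.c_out), dtype=np.float32)
        y[...] = self.b.value
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                y += xp[:, i : i + H, j : j + W, :] @ wv[i, j]
        if train:
            self._xp = xp
        return y

    def backward(self, grad):
        xp = self._xp
        k, p = self.k, self.k // 2
        N = grad.shape[0]
        H, W = grad.shape[1], grad.shape[2]
        wv = self.w.value
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i : i + H, j : j + W, :]
                self.w.grad[i, j] += np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i : i + H, j : j + W, :] += grad @ wv[i, j].T
        self.b.grad += grad.sum(axis=(0, 1, 2))
        self._xp = None
        if not p:
            return dxp
        if self.pad_mode == "zeros":
            return dxp[:, p : p + H, p : p + W, :]
        # fold reflected margins back onto their source rows/columns, in
        # reverse order of the padding (np.pad pads axes sequentially;
        # reflect: padded[i] = x[p - i] on the leading edge)
        for j in range(p):
            dxp[:, :, 2 * p - j, :] += dxp[:, :, j, :]
            dxp[:, :, -(2 * p - j) - 1, :] += dxp[:, :, -(j + 1), :]
        dxp = dxp[:, :, p : p + W, :]
        for i in range(p):
            dxp[:, 2 * p - i, :, :] += dxp[:, i, :, :]
            dxp[:, -(2 * p - i) - 1, :, :] += dxp[:, -(i + 1), :, :]
        return dxp[:, p : p + H, :, :]


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool = False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Module):
    """2x2 max pooling, stride 2; requires even spatial dims."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x, train: bool = False):
        N, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        win = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(N, H // 2, W // 2, C, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (N, H, W, C)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        N, H, W, C = self._shape
        d = np.zeros((N, H // 2, W // 2, C, 4), dtype=np.float32)
        np.put_along_axis(d, self._idx[..., None], grad[..., None], axis=-1)
        d = d.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(d.reshape(N, H, W, C))


class Upsample2d(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train: bool = False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, grad):
        N, H, W, C = grad.shape
        return grad.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(he_init(rng, (n_out, n_in), n_in))
        self.b = Param(np.zeros(n_out, dtype=np.float32))
        self._x = None

    def forward(self, x, train: bool = False):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        self._x = None
        return grad @ self.w.value


class GlobalAvgPool(Module):
    """NHWC -> NC mean over the spatial axes."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train: bool = False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        N, H, W, C = self._shape
        return np.broadcast_to(grad[:, None, None, :], (N, H, W, C)) / (H * W)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, train: bool = False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, grad):
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


# ---- (de)serialization helpers -------------------------------------------


def state_dict(module: Module) -> list[np.ndarray]:
    return [p.value.copy() for p in module.params()]


def load_state_dict(module: Module, state: list[np.ndarray]) -> None:
    params = module.params()
    if len(params) != len(state):
        raise ValueError(f"state has {len(state)} arrays, model {len(params)} params")
    for p, v in zip(params, state):
        if p.value.shape != v.shape:
            raise ValueError(f"shape mismatch {p.value.shape} vs {v.shape}")
        p.value[...] = np.asarray(v, dtype=np.float32)
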