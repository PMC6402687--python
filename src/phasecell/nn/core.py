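"""Minimal numpy neural-network engine.

Layers follow a forward/backward protocol with explicit caches so the same
module graph can be trained with plain reverse-mode differentiation.  All
convolution arithmetic is done through im2col/col2im and BLAS matmuls; inputs
and parameters are float32 by default (float64 is supported for gradient
checking).

Conventions: image batches are (B, C, H, W); ``Conv2d`` weights are
(C_out, C_in, k, k); ``ConvTranspose2d`` weights are (C_in, C_out, k, k) so
that a transposed convolution is exactly the data-gradient of the matching
forward convolution.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "L2Normalize",
    "conv_out_size",
    "convT_out_size",
]


def conv_out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def convT_out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n - 1) * stride - 2 * pad + k


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """View a padded (B,C,H,W) array as (B,C,k,k,oh,ow) sliding windows."""
    B, C, H, W = xp.shape
    oh = (H - k) // stride + 1
    ow = (W - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (B, C, k, k, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )


def im2col(x: np.ndarray, k: int, stride: int, pad: int, pad_value: float = 0.0) -> np.ndarray:
    """(B,C,H,W) -> (B, C*k*k, oh*ow) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value)
    B, C = x.shape[:2]
    w = _windows(x, k, stride)
    oh, ow = w.shape[4], w.shape[5]
    return np.ascontiguousarray(w).reshape(B, C * k * k, oh * ow)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col`."""
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    oh = (Hp - k) // stride + 1
    ow = (Wp - k) // stride + 1
    out = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    cols6 = cols.reshape(B, C, k, k, oh, ow)
    for i in range(k):
        hi = i + stride * oh
        for j in range(k):
            wj = j + stride * ow
            out[:, :, i:hi:stride, j:wj:stride] += cols6[:, :, i, j]
    if pad:
        out = out[:, :, pad:pad + H, pad:pad + W]
    return out


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)

    # -- checkpointing ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.params()
        if len(state) != len(own):
            raise ValueError(f"state has {len(state)} arrays, module has {len(own)}")
        for i, p in enumerate(own):
            arr = state[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for param {i}: {arr.shape} vs {p.value.shape}")
            p.value[...] = arr


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(_he_normal(rng, (n_out, n_in), n_in, dtype), "W")
        self.b = Param(np.zeros(n_out, dtype=dtype), "b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if x.ndim != 2 or x.shape[1] != self.W.value.shape[1]:
            raise ValueError(
                f"Linear expects (B, {self.W.value.shape[1]}), got {x.shape}"
            )
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, gout):
        self.W.grad += gout.T @ self._x
        self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        fan_in = c_in * k * k
        self.W = Param(_he_normal(rng, (c_out, c_in, k, k), fan_in, dtype), "W")
        self.b = Param(np.zeros(c_out, dtype=dtype), "b")
        self._cols = None
        self._x_shape = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != self.c_in:
            raise ValueError(f"Conv2d expects (B,{self.c_in},H,W), got {x.shape}")
        B, _, H, W = x.shape
        oh = conv_out_size(H, self.k, self.stride, self.pad)
        ow = conv_out_size(W, self.k, self.stride, self.pad)
        cols = im2col(x, self.k, self.stride, self.pad)
        self._cols, self._x_shape = cols, x.shape
        Wm = self.W.value.reshape(self.c_out, -1)
        out = np.matmul(Wm[None], cols)  # (B, c_out, oh*ow)
        out += self.b.value[None, :, None]
        return out.reshape(B, self.c_out, oh, ow)

    def backward(self, gout):
        B = gout.shape[0]
        gm = gout.reshape(B, self.c_out, -1)
        self.W.grad += np.tensordot(gm, self._cols, axes=([0, 2], [0, 2])).reshape(self.W.value.shape)
        self.b.grad += gm.sum(axis=(0, 2))
        Wm = self.W.value.reshape(self.c_out, -1)
        gcols = np.matmul(Wm.T[None], gm)
        return col2im(gcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        fan_in = c_in * k * k
        self.W = Param(_he_normal(rng, (c_in, c_out, k, k), fan_in, dtype), "W")
        self.b = Param(np.zeros(c_out, dtype=dtype), "b")
        self._xm = None
        self._in_shape = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != self.c_in:
            raise ValueError(f"ConvTranspose2d expects (B,{self.c_in},H,W), got {x.shape}")
        B, _, H, W = x.shape
        oh = convT_out_size(H, self.k, self.stride, self.pad)
        ow = convT_out_size(W, self.k, self.stride, self.pad)
        xm = x.reshape(B, self.c_in, H * W)
        self._xm, self._in_shape = xm, x.shape
        Wm = self.W.value.reshape(self.c_in, -1)  # (c_in, c_out*k*k)
        cols = np.matmul(Wm.T[None], xm)  # (B, c_out*k*k, H*W)
        out = col2im(cols, (B, self.c_out, oh, ow), self.k, self.stride, self.pad)
        out += self.b.value[None, :, None, None]
        return out

    def backward(self, gout):
        B, _, H, W = self._in_shape
        gcols = im2col(gout, self.k, self.stride, self.pad)  # (B, c_out*k*k, H*W)
        self.W.grad += np.tensordot(self._xm, gcols, axes=([0, 2], [0, 2])).reshape(self.W.value.shape)
        self.b.grad += gout.sum(axis=(0, 2, 3))
        Wm = self.W.value.reshape(self.c_in, -1)
        gx = np.matmul(Wm[None], gcols)
        return gx.reshape(self._in_shape)


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int, pad: int):
        self.k, self.stride, self.pad = k, stride, pad
        self._argmax = None
        self._x_shape = None
        self._out_hw = None

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        oh = conv_out_size(H, self.k, self.stride, self.pad)
        ow = conv_out_size(W, self.k, self.stride, self.pad)
        cols = im2col(x, self.k, self.stride, self.pad, pad_value=-np.inf)
        cols = cols.reshape(B, C, self.k * self.k, oh * ow)
        self._argmax = cols.argmax(axis=2)
        self._x_shape, self._out_hw = x.shape, (oh, ow)
        out = np.take_along_axis(cols, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]
        return out.reshape(B, C, oh, ow)

    def backward(self, gout):
        B, C, H, W = self._x_shape
        oh, ow = self._out_hw
        gcols = np.zeros((B, C, self.k * self.k, oh * ow), dtype=gout.dtype)
        np.put_along_axis(gcols, self._argmax[:, :, None, :],
                          gout.reshape(B, C, 1, oh * ow), axis=2)
        return col2im(gcols.reshape(B, C * self.k * self.k, oh * ow),
                      self._x_shape, self.k, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype), "gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gout):
        xhat, inv, shape = self._cache
        B, C, H, W = shape
        n = B * H * W
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxhat_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / n) * (n * g - gsum - xhat * gxhat_sum)


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout):
        return np.where(self._mask, gout, self.slope * gout)


class Tanh(Module):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout):
        return gout * (1 - self._y ** 2)


class Sigmoid(Module):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1 - self._y)


class Flatten(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Reshape(Module):
    def __init__(self, *shape: int):
        self.shape = shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, gout):
        return gout.reshape(self._in_shape)


class L2Normalize(Module):
    """Project row vectors onto the unit sphere (with a small floor on the norm)."""

    def __init__(self, eps: float = 1e-8):
        self.eps = eps

    def forward(self, x, train=True):
        norm = np.sqrt((x ** 2).sum(axis=1, keepdims=True)) + self.eps
        self._y, self._norm = x / norm, norm
        return self._y

    def backward(self, gout):
        dot = (gout * self._y).sum(axis=1, keepdims=True)
        return (gout - self._y * dot) / self._norm
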