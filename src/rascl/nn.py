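"""Minimal numpy neural-network engine used by the encoders and MLP heads.

Implements exactly the layers the package needs — 2-D convolution, batch
normalisation, max / global-average pooling, fully connected layers, ReLU —
with analytic backpropagation and an Adam optimiser.  All computation is
float64 numpy; convolutions use an im2col/GEMM formulation so the desk-scale
encoders train in seconds on a single CPU core.

Conventions: image batches are NCHW float arrays; every layer caches what its
backward pass needs during ``forward(train=True)`` and releases it on the next
call.  Parameters are held in :class:`Parameter` objects so optimisers and
state (de)serialisation can treat every module uniformly.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Linear",
    "ReLU",
    "Conv2d",
    "BatchNorm2d",
    "MaxPool2d",
    "GlobalAvgPool",
    "GridAvgPool",
    "Flatten",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "state_hash",
]


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: ``forward`` caches, ``backward`` consumes the cache."""

    def parameters(self) -> list[Parameter]:
        return []

    def buffer_refs(self) -> list[tuple["Module", str]]:
        """Non-trainable state (e.g. batch-norm running stats) as (owner, attr)."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)

    # -- state management ---------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        params = [p.data.copy() for p in self.parameters()]
        buffers = [getattr(owner, name).copy() for owner, name in self.buffer_refs()]
        return params + buffers

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        buffers = self.buffer_refs()
        if len(state) != len(params) + len(buffers):
            raise ValueError(
                f"state has {len(state)} arrays, module expects "
                f"{len(params)} params + {len(buffers)} buffers"
            )
        for p, s in zip(params, state):
            if p.data.shape != np.shape(s):
                raise ValueError(f"shape mismatch: {p.data.shape} vs {np.shape(s)}")
            p.data = np.asarray(s, dtype=np.float64).copy()
        for (owner, name), s in zip(buffers, state[len(params):]):
            setattr(owner, name, np.asarray(s, dtype=np.float64).copy())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad.fill(0.0)

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def state_hash(module: Module) -> str:
    """SHA-256 of a module's parameter bytes; used for freeze contracts."""
    h = hashlib.sha256()
    for p in module.parameters():
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def buffer_refs(self):
        out: list[tuple[Module, str]] = []
        for layer in self.layers:
            out.extend(layer.buffer_refs())
        return out

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))
        self._x: np.ndarray | None = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, grad_out):
        x = self._x
        self.weight.grad += x.T @ grad_out
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.data.T


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad_out):
        return grad_out * self._mask


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N*OH*OW, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # (N,C,OH,OW,kh,kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols, x_shape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    dcols = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
    ):
        k = kernel_size
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(fan_in, out_channels)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.padding = padding
        self._cache = None
        self.last_output: np.ndarray | None = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=True):
        n = x.shape[0]
        cols, oh, ow = _im2col(x, self.kernel_size, self.kernel_size, self.stride, self.padding)
        out = cols @ self.weight.data
        if self.bias is not None:
            out += self.bias.data
        out = out.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape, oh, ow)
        self.last_output = out
        return out

    def backward(self, grad_out):
        cols, x_shape, oh, ow = self._cache
        n = x_shape[0]
        g = grad_out.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_channels)
        self.weight.grad += cols.T @ g
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        dcols = g @ self.weight.data.T
        return _col2im(
            dcols, x_shape, self.kernel_size, self.kernel_size, self.stride, self.padding, oh, ow
        )


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def buffer_refs(self):
        return [(self, "running_mean"), (self, "running_var")]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad_out):
        xhat, inv = self._cache
        m = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        g = grad_out * self.gamma.data[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3))[None, :, None, None]
        gxsum = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (inv[None, :, None, None] / m) * (m * g - gsum - xhat * gxsum)
        return dx


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int):
        self.k = kernel_size
        self.stride = stride
        self._cache = None

    def forward(self, x, train=True):
        cols, oh, ow = _im2col(
            x.reshape(x.shape[0] * x.shape[1], 1, x.shape[2], x.shape[3]),
            self.k,
            self.k,
            self.stride,
            pad=0,
        )
        idx = cols.argmax(axis=1)
        out = cols[np.arange(cols.shape[0]), idx]
        n, c = x.shape[0], x.shape[1]
        if train:
            self._cache = (idx, x.shape, oh, ow)
        return out.reshape(n, c, oh, ow)

    def backward(self, grad_out):
        idx, x_shape, oh, ow = self._cache
        n, c, h, w = x_shape
        dcols = np.zeros((n * c * oh * ow, self.k * self.k))
        dcols[np.arange(dcols.shape[0]), idx] = grad_out.reshape(-1)
        dx = _col2im(dcols, (n * c, 1, h, w), self.k, self.k, self.stride, 0, oh, ow)
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Module):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out):
        n, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None], (n, c, h, w)) / (h * w)


class GridAvgPool(Module):
    """(N,C,H,W) -> (N, C*g*g): average pool onto a g x g grid, flattened.

    A coarse spatial pooling that keeps location information (e.g. where in
    the scan a feature fired) while remaining input-size agnostic; requires
    H and W divisible by g.
    """

    def __init__(self, grid: int):
        self.grid = grid
        self._shape = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        g = self.grid
        if h % g or w % g:
            raise ValueError(f"spatial dims {h}x{w} not divisible by grid {g}")
        if train:
            self._shape = x.shape
        pooled = x.reshape(n, c, g, h // g, g, w // g).mean(axis=(3, 5))
        return pooled.reshape(n, c * g * g)

    def backward(self, grad_out):
        n, c, h, w = self._shape
        g = self.grid
        gh, gw = h // g, w // g
        grad = grad_out.reshape(n, c, g, 1, g, 1) / (gh * gw)
        return np.broadcast_to(grad, (n, c, g, gh, g, gw)).reshape(n, c, h, w)


class Flatten(Module):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Adam:
    """Adam optimiser over a fixed parameter list."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          sample_weight: np.ndarray | None = None):
    """Weighted mean cross-entropy over integer labels; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    nll = -np.log(p[np.arange(n), labels] + eps)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    if sample_weight is None:
        return nll.mean(), grad / n
    w = np.asarray(sample_weight, dtype=np.float64)
    wsum = w.sum()
    return float((w * nll).sum() / wsum), grad * (w / wsum)[:, None]
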