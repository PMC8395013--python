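"""Minimal NumPy layer stack with explicit backward passes.

Every layer is stateless between calls: ``forward`` returns ``(y, cache)`` and
``backward(dy, cache)`` accumulates parameter gradients and returns the input
gradient.  Per-call caches make it safe to run a module several times inside a
single optimization step (the cycle-consistent routine pushes images through
each generator more than once before any backward pass).

Arrays are NCHW float32.  Padding follows the "same" convention: for stride s
the output has ``ceil(H/s)`` rows and the total pad is split floor/ceil.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "InstanceNorm2d",
    "Swish",
    "Sigmoid",
    "MaxPool2d",
    "UpsampleNearest2d",
    "Adam",
]


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: children discovered via attributes and lists of modules."""

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Param):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match module parameters")
        for p, v in zip(params, state):
            p.value[...] = v


def _same_pad(n: int, k: int, stride: int) -> tuple[int, int]:
    out = math.ceil(n / stride)
    total = max((out - 1) * stride + k - n, 0)
    return total // 2, total - total // 2


class Conv2d(Module):
    """2D convolution (cross-correlation) with "same" padding.

    Implemented as a shift-and-add over kernel offsets: k*k small matrix
    products instead of an im2col buffer, which keeps memory flat even for the
    11x11 inception branches.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, use_bias: bool = True,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        w = rng.normal(0.0, init_std, size=(out_channels, in_channels,
                                            kernel_size, kernel_size))
        self.weight = Param(w, "conv.weight")
        self.bias = Param(np.zeros(out_channels), "conv.bias") if use_bias else None

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        k, s = self.kernel_size, self.stride
        ph = _same_pad(h, k, s)
        pw = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        ho = math.ceil(h / s)
        wo = math.ceil(w / s)
        out = np.zeros((self.out_channels, n, ho, wo), dtype=np.float32)
        W = self.weight.value
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di:di + (ho - 1) * s + 1:s, dj:dj + (wo - 1) * s + 1:s]
                out += np.tensordot(W[:, :, di, dj], xs, axes=([1], [1]))
        y = np.ascontiguousarray(out.transpose(1, 0, 2, 3))
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        cache = (xp, x.shape, (ph, pw))
        return y, cache

    def backward(self, dy: np.ndarray, cache):
        xp, x_shape, (ph, pw) = cache
        n, c, h, w = x_shape
        k, s = self.kernel_size, self.stride
        ho, wo = dy.shape[2], dy.shape[3]
        W = self.weight.value
        dxp = np.zeros_like(xp)
        dyt = np.ascontiguousarray(dy.transpose(1, 0, 2, 3))  # (Co,N,Ho,Wo)
        for di in range(k):
            for dj in range(k):
                sl = (slice(None), slice(None),
                      slice(di, di + (ho - 1) * s + 1, s),
                      slice(dj, dj + (wo - 1) * s + 1, s))
                xs = xp[sl]
                # (Co,Ci) gradient for this offset
                self.weight.grad[:, :, di, dj] += np.tensordot(
                    dyt, xs, axes=([1, 2, 3], [0, 2, 3]))
                dxp[sl] += np.tensordot(W[:, :, di, dj], dyt,
                                        axes=([0], [0])).transpose(1, 0, 2, 3)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, ph[0]:ph[0] + h, pw[0]:pw[0] + w]


class InstanceNorm2d(Module):
    """Per-sample per-channel standardization over spatial positions with a
    learned scale and shift (scale init 1, shift init 0)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = Param(np.ones(channels), "in.gamma")
        self.beta = Param(np.zeros(channels), "in.beta")

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]
        return y, (xhat, inv)

    def backward(self, dy: np.ndarray, cache):
        xhat, inv = cache
        m = dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        t1 = dxhat.sum(axis=(2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
        return (dxhat - t1 / m - xhat * t2 / m) * inv


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Swish(Module):
    """x * sigmoid(x)."""

    def forward(self, x: np.ndarray):
        s = _sigmoid(x)
        return x * s, (x, s)

    def backward(self, dy: np.ndarray, cache):
        x, s = cache
        return dy * (s + x * s * (1.0 - s))


class Sigmoid(Module):
    def forward(self, x: np.ndarray):
        y = _sigmoid(x)
        return y, y

    def backward(self, dy: np.ndarray, cache):
        y = cache
        return dy * y * (1.0 - y)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2 (even input sizes only)."""

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        return y, (idx, x.shape)

    def backward(self, dy: np.ndarray, cache):
        idx, (n, c, h, w) = cache
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        dx = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class UpsampleNearest2d(Module):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray):
        y = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
        return y, x.shape

    def backward(self, dy: np.ndarray, cache):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class Adam:
    """ADAM with bias correction; one optimizer per model."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
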