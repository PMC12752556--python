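"""Minimal CPU neural-network layers with explicit forward/backward passes.

All tensors are float32 NCHW. Every layer owns its parameters in ``self.params``
and accumulates gradients of the same shape in ``self.grads``. ``backward``
consumes the upstream gradient and returns the gradient w.r.t. the layer input.
Initialisation is driven by an explicit ``numpy.random.Generator`` so that two
builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU",
    "GELU",
    "MaxPool2d",
    "UpsampleNearest2d",
    "Linear",
    "GlobalAvgPool",
]


class Module:
    """Base class: parameter bookkeeping plus train/eval mode."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def train(self):
        self.training = True

    def eval(self):
        self.training = False

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _pad_hw(x, ph, pw):
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


class Conv2d(Module):
    """Dense 2-D convolution via im2col.

    ``padding`` defaults to 'same' behaviour for odd kernels at stride 1 when
    set to None; pass an int for explicit padding.
    """

    def __init__(self, cin, cout, k, stride=1, padding=None, dilation=1,
                 bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation = stride, dilation
        eff = (k - 1) * dilation + 1
        self.padding = (eff - 1) // 2 if padding is None else padding
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.params["w"] = w.astype(np.float32)
        self.grads["w"] = np.zeros_like(self.params["w"])
        if bias:
            self.params["b"] = np.zeros(cout, dtype=np.float32)
            self.grads["b"] = np.zeros_like(self.params["b"])

    def _im2col(self, xp):
        k, d, s = self.k, self.dilation, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, ((k - 1) * d + 1,) * 2, axis=(2, 3))
        win = win[:, :, ::s, ::s, ::d, ::d]  # (N,C,Ho,Wo,k,k)
        return win

    def forward(self, x):
        xp = _pad_hw(x, self.padding, self.padding)
        win = self._im2col(xp)
        n, c, ho, wo = win.shape[0], win.shape[1], win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * self.k * self.k)
        wmat = self.params["w"].reshape(self.cout, -1)
        out = cols @ wmat.T
        if "b" in self.params:
            out += self.params["b"]
        self._cache = (cols, x.shape, xp.shape, (n, ho, wo))
        return np.ascontiguousarray(out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy):
        cols, xshape, xpshape, (n, ho, wo) = self._cache
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.grads["w"] += (dyf.T @ cols).reshape(self.params["w"].shape)
        if "b" in self.params:
            self.grads["b"] += dyf.sum(axis=0)
        dcols = dyf @ self.params["w"].reshape(self.cout, -1)
        dcols = dcols.reshape(n, ho, wo, self.cin, self.k, self.k)
        dxp = np.zeros(xpshape, dtype=np.float32)
        s, d = self.stride, self.dilation
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i * d:i * d + ho * s:s, j * d:j * d + wo * s:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        p = self.padding
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp if dxp.shape == xshape else dxp[:, :, :xshape[2], :xshape[3]]


class DepthwiseConv2d(Module):
    """Per-channel (grouped, groups == channels) convolution."""

    def __init__(self, c, k, dilation=1, bias=True, rng=None):
        super().__init__()
        self.c, self.k, self.dilation = c, k, dilation
        eff = (k - 1) * dilation + 1
        self.padding = (eff - 1) // 2
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / (k * k)),
                                      size=(c, k, k)).astype(np.float32)
        self.grads["w"] = np.zeros_like(self.params["w"])
        if bias:
            self.params["b"] = np.zeros(c, dtype=np.float32)
            self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x):
        d, k = self.dilation, self.k
        xp = _pad_hw(x, self.padding, self.padding)
        win = np.lib.stride_tricks.sliding_window_view(xp, ((k - 1) * d + 1,) * 2, axis=(2, 3))
        win = win[..., ::d, ::d]  # (N,C,H,W,k,k)
        out = np.einsum("nchwij,cij->nchw", win, self.params["w"], optimize=True)
        if "b" in self.params:
            out += self.params["b"][None, :, None, None]
        self._cache = (win, x.shape, xp.shape)
        return out.astype(np.float32)

    def backward(self, dy):
        win, xshape, xpshape = self._cache
        self.grads["w"] += np.einsum("nchwij,nchw->cij", win, dy, optimize=True)
        if "b" in self.params:
            self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros(xpshape, dtype=np.float32)
        d = self.dilation
        h, w = dy.shape[2], dy.shape[3]
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i * d:i * d + h, j * d:j * d + w] += \
                    dy * self.params["w"][None, :, i, j, None, None]
        p = self.padding
        return dxp[:, :, p:-p, p:-p] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.grads["gamma"] = np.zeros(c, dtype=np.float32)
        self.grads["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None]).astype(np.float32)

    def backward(self, dy):
        xhat, inv, xshape = self._cache
        m = xshape[0] * xshape[2] * xshape[3]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        if not self.training:
            return (dxhat * inv[None, :, None, None]).astype(np.float32)
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = inv[None, :, None, None] / m * (m * dxhat - t1 - xhat * t2)
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


_GC = np.float32(np.sqrt(2.0 / np.pi))


class GELU(Module):
    """tanh-approximation GELU."""

    def forward(self, x):
        self._x = x
        inner = _GC * (x + 0.044715 * x ** 3)
        self._t = np.tanh(inner)
        return (0.5 * x * (1.0 + self._t)).astype(np.float32)

    def backward(self, dy):
        x, t = self._x, self._t
        dinner = _GC * (1.0 + 3 * 0.044715 * x ** 2)
        dx = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
        return (dy * dx).astype(np.float32)


class MaxPool2d(Module):
    """2x2, stride 2; input H, W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr.reshape(n, c, h, w))


class UpsampleNearest2d(Module):
    def __init__(self, factor=2):
        super().__init__()
        self.f = factor

    def forward(self, x):
        self._shape = x.shape
        return np.repeat(np.repeat(x, self.f, axis=2), self.f, axis=3)

    def backward(self, dy):
        n, c, h, w = self._shape
        return dy.reshape(n, c, h, self.f, w, self.f).sum(axis=(3, 5)).astype(np.float32)


class Linear(Module):
    def __init__(self, cin, cout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(0, np.sqrt(2.0 / cin),
                                      size=(cout, cin)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dy):
        self.grads["w"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return (dy @ self.params["w"]).astype(np.float32)


class GlobalAvgPool(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return (np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)).astype(np.float32)
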