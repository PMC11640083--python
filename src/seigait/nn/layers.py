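"""Layers with explicit forward/backward passes, float32 throughout.

Conventions: image tensors are (B, C, H, W); token tensors are (B, T, D).
``forward(x, training, rng)`` caches what ``backward(grad)`` needs;
``backward`` accumulates parameter gradients into ``Param.grad`` and
returns the gradient with respect to the input.  A fresh ``rng`` is the
only source of randomness (dropout masks), so runs are reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GELU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Dropout",
    "Flatten",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "softmax_cross_entropy",
]

F32 = np.float32


class Param:
    """A learnable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # whether weight decay applies (not for biases/norms)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def num_params(self) -> int:
        return sum(p.size for p in self.params())


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Conv2d(Layer):
    """im2col convolution with optional stride and same/valid padding."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, pad=None, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = (kernel // 2) if pad is None else pad
        fan_in = in_ch * kernel * kernel
        self.weight = Param(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Param(np.zeros(out_ch, dtype=F32), decay=False) if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False, rng=None):
        x = x.astype(F32)
        b, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (B, C, oh, ow, k, k) -> (B, oh*ow, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * k * k)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, x.shape, (oh, ow))
        return out.reshape(b, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xshape, (oh, ow) = self._cache
        b, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(b, oh * ow, self.out_ch)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        self.weight.grad += (
            np.einsum("blo,blk->ok", g, cols).reshape(self.weight.value.shape)
        )
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 1))
        dcols = (g @ wmat).reshape(b, oh, ow, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, ch, eps=1e-5, momentum=0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(ch, dtype=F32), decay=False)
        self.beta = Param(np.zeros(ch, dtype=F32), decay=False)
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False, rng=None):
        x = x.astype(F32)
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(F32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape) if training else None
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, inv, xshape = self._cache
        b, c, h, w = xshape
        n = b * h * w
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gyz = self.gamma.value[None, :, None, None] * grad
        sum_gyz = gyz.sum(axis=(0, 2, 3), keepdims=True)
        sum_gyz_xhat = (gyz * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            inv[None, :, None, None]
            * (gyz - sum_gyz / n - xhat * sum_gyz_xhat / n)
        ).astype(F32)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, grad):
        return np.where(self._mask, grad, 0).astype(F32)


class GELU(Layer):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x, training=False, rng=None):
        x = x.astype(F32)
        self._x = x
        self._phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0))).astype(F32)
        return (x * self._phi).astype(F32)

    def backward(self, grad):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return (grad * (self._phi + x * pdf)).astype(F32)


class MaxPool2d(Layer):
    """2x2 max pooling (stride 2); odd trailing rows/cols are cropped."""

    def forward(self, x, training=False, rng=None):
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        blocks = xc.reshape(b, c, h2, 2, w2, 2)
        out = blocks.max(axis=(3, 5))
        # distribute gradient uniformly over tied maxima (deterministic)
        mask = blocks == out[:, :, :, None, :, None]
        self._cache = (mask, mask.sum(axis=(3, 5), keepdims=True), x.shape)
        return out.astype(F32)

    def backward(self, grad):
        mask, counts, xshape = self._cache
        b, c, h, w = xshape
        h2, w2 = mask.shape[2], mask.shape[4]
        g = grad[:, :, :, None, :, None] * mask / counts
        dx = np.zeros(xshape, dtype=F32)
        dx[:, :, : 2 * h2, : 2 * w2] = g.reshape(b, c, 2 * h2, 2 * w2)
        return dx


class GlobalAvgPool2d(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(F32)

    def backward(self, grad):
        b, c, h, w = self._shape
        return (np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)).astype(
            F32
        )


class Dropout(Layer):
    def __init__(self, p=0.5):
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p <= 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        return (x * self._mask).astype(F32)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(F32)


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    """Affine map on the last axis; works for (B, D) and (B, T, D) inputs."""

    def __init__(self, in_dim, out_dim, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Param(np.zeros(out_dim, dtype=F32), decay=False) if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False, rng=None):
        x = x.astype(F32)
        self._x = x
        out = x @ self.weight.value
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, grad):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.weight.grad += x2.T @ g2
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        return (grad @ self.weight.value.T).reshape(self._x.shape)


class LayerNorm(Layer):
    def __init__(self, dim, eps=1e-6):
        self.eps = eps
        self.gamma = Param(np.ones(dim, dtype=F32), decay=False)
        self.beta = Param(np.zeros(dim, dtype=F32), decay=False)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False, rng=None):
        x = x.astype(F32)
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (grad * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += grad.reshape(-1, d).sum(axis=0)
        gy = grad * self.gamma.value
        return (
            inv
            * (
                gy
                - gy.mean(axis=-1, keepdims=True)
                - xhat * (gy * xhat).mean(axis=-1, keepdims=True)
            )
        ).astype(F32)


class MultiHeadSelfAttention(Layer):
    """Standard multi-head self-attention on (B, T, D) tokens."""

    def __init__(self, dim, heads, rng=None):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        rng = rng or np.random.default_rng(0)
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.scale = 1.0 / np.sqrt(self.dh)

    def params(self):
        return self.qkv.params() + self.proj.params()

    def forward(self, x, training=False, rng=None):
        b, t, d = x.shape
        qkv = self.qkv.forward(x, training, rng)  # (B, T, 3D)
        qkv = qkv.reshape(b, t, 3, self.heads, self.dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (B, H, T, dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        scores -= scores.max(axis=-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        out = attn @ v  # (B, H, T, dh)
        self._cache = (q, k, v, attn)
        merged = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj.forward(merged, training, rng)

    def backward(self, grad):
        q, k, v, attn = self._cache
        b, h, t, dh = q.shape
        dmerged = self.proj.backward(grad).reshape(b, t, h, dh).transpose(0, 2, 1, 3)
        dattn = dmerged @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dmerged
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dq = (dscores @ k) * self.scale
        dk = (dscores.transpose(0, 1, 3, 2) @ q) * self.scale
        dqkv = np.stack([dq, dk, dv])  # (3, B, H, T, dh)
        dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(b, t, 3 * self.dim)
        return self.qkv.backward(dqkv)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(F32)
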