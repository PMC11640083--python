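"""Composite blocks: residual basic blocks and transformer encoder blocks."""

from __future__ import annotations

import numpy as np

from seigait.nn.layers import (
    F32,
    BatchNorm2d,
    Conv2d,
    GELU,
    Layer,
    LayerNorm,
    Linear,
    MultiHeadSelfAttention,
    Param,
    ReLU,
    Sequential,
)

__all__ = ["BasicBlock", "TransformerBlock", "VisionTransformerBackbone"]


class BasicBlock(Layer):
    """Two 3x3 convs with a shortcut; the residual form y = F(x) + x."""

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, bias=False, rng=rng),
                BatchNorm2d(out_ch),
            )
        else:
            self.shortcut = None

    def params(self):
        out = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x, training=False, rng=None):
        y = self.conv1.forward(x, training, rng)
        y = self.bn1.forward(y, training, rng)
        y = self.relu1.forward(y, training, rng)
        y = self.conv2.forward(y, training, rng)
        y = self.bn2.forward(y, training, rng)
        sc = x if self.shortcut is None else self.shortcut.forward(x, training, rng)
        return self.relu2.forward(y + sc, training, rng)

    def backward(self, grad):
        grad = self.relu2.backward(grad)
        gy, gsc = grad, grad
        gy = self.bn2.backward(gy)
        gy = self.conv2.backward(gy)
        gy = self.relu1.backward(gy)
        gy = self.bn1.backward(gy)
        gy = self.conv1.backward(gy)
        if self.shortcut is not None:
            gsc = self.shortcut.backward(gsc)
        return gy + gsc


class TransformerBlock(Layer):
    """Pre-norm encoder block: x + MHSA(LN(x)); then x + MLP(LN(x))."""

    def __init__(self, dim, heads, mlp_dim, rng=None):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_dim, rng=rng)
        self.act = GELU()
        self.fc2 = Linear(mlp_dim, dim, rng=rng)

    def params(self):
        return (
            self.norm1.params()
            + self.attn.params()
            + self.norm2.params()
            + self.fc1.params()
            + self.fc2.params()
        )

    def forward(self, x, training=False, rng=None):
        y = self.attn.forward(self.norm1.forward(x, training, rng), training, rng)
        x = x + y
        z = self.fc1.forward(self.norm2.forward(x, training, rng), training, rng)
        z = self.fc2.forward(self.act.forward(z, training, rng), training, rng)
        return x + z

    def backward(self, grad):
        gz = self.fc2.backward(grad)
        gz = self.act.backward(gz)
        gz = self.fc1.backward(gz)
        gz = self.norm2.backward(gz)
        grad = grad + gz
        gy = self.attn.backward(grad)
        gy = self.norm1.backward(gy)
        return grad + gy


class VisionTransformerBackbone(Layer):
    """Patch embedding + class token + learned positions + encoder stack.

    Classification reads the class token through a final layer norm and a
    linear head (handled by the caller).
    """

    def __init__(self, image_size, patch, in_ch, dim, depth, heads, mlp_dim, rng=None):
        if image_size % patch:
            raise ValueError(f"image size {image_size} not divisible by patch {patch}")
        rng = rng or np.random.default_rng(0)
        self.patch, self.in_ch, self.dim = patch, in_ch, dim
        self.tokens = (image_size // patch) ** 2
        self.embed = Linear(in_ch * patch * patch, dim, rng=rng)
        self.cls_token = Param(
            rng.normal(0, 0.02, size=(1, 1, dim)).astype(F32), decay=False
        )
        self.pos_embed = Param(
            rng.normal(0, 0.02, size=(1, self.tokens + 1, dim)).astype(F32),
            decay=False,
        )
        self.blocks = [TransformerBlock(dim, heads, mlp_dim, rng=rng) for _ in range(depth)]
        self.norm = LayerNorm(dim)

    def params(self):
        out = self.embed.params() + [self.cls_token, self.pos_embed]
        for blk in self.blocks:
            out += blk.params()
        return out + self.norm.params()

    def _patchify(self, x):
        b, c, h, w = x.shape
        p = self.patch
        gh, gw = h // p, w // p
        x = x.reshape(b, c, gh, p, gw, p).transpose(0, 2, 4, 1, 3, 5)
        return x.reshape(b, gh * gw, c * p * p)

    def forward(self, x, training=False, rng=None):
        self._xshape = x.shape
        tok = self.embed.forward(self._patchify(x.astype(F32)), training, rng)
        b = tok.shape[0]
        cls = np.broadcast_to(self.cls_token.value, (b, 1, self.dim)).astype(F32)
        seq = np.concatenate([cls, tok], axis=1) + self.pos_embed.value
        for blk in self.blocks:
            seq = blk.forward(seq, training, rng)
        seq = self.norm.forward(seq, training, rng)
        self._b = b
        return seq[:, 0]  # class token

    def backward(self, grad):
        b, c, h, w = self._xshape
        gseq = np.zeros((b, self.tokens + 1, self.dim), dtype=F32)
        gseq[:, 0] = grad
        gseq = self.norm.backward(gseq)
        for blk in reversed(self.blocks):
            gseq = blk.backward(gseq)
        self.pos_embed.grad += gseq.sum(axis=0, keepdims=True)
        self.cls_token.grad += gseq[:, :1].sum(axis=0, keepdims=True)
        gtok = self.embed.backward(gseq[:, 1:])
        p = self.patch
        gh, gw = h // p, w // p
        gx = gtok.reshape(b, gh, gw, c, p, p).transpose(0, 3, 1, 4, 2, 5)
        return gx.reshape(b, c, h, w)
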