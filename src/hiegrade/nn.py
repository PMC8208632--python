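"""Minimal trainable CNN layers in numpy (NCHW layout, float32).

Implements exactly what the grading network needs: 2-D convolution with
size-preserving ("same") padding and optional stride, ReLU, max-pooling
with ceil(size/stride) output, batch normalisation with running statistics,
global average pooling, dense layers, and a softmax cross-entropy head.
Each layer exposes forward(x, training) / backward(grad) and its
parameters as (name, value, grad) triples, so an SGD loop can update them
in place.

Convolution runs as im2col into a (batch, K, positions) buffer -- each
kernel-offset copy is a contiguous write -- followed by one batched BLAS
matrix product, so a single CPU core trains the grading network in
minutes.  Layers that read the raw image can skip the input-gradient pass
(``needs_input_grad=False``), which is the expensive half of backward.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "BatchNorm2d",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "softmax",
    "cross_entropy",
]


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Output size ceil(size/stride) and the (before, after) padding."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


class Layer:
    def parameters(self):  # -> list[tuple[str, ndarray, ndarray]]
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _buffer(self, key: str, shape, fill=None) -> np.ndarray:
        """Reusable float32 scratch view (fresh large allocations every
        step would spend more time page-faulting than computing).  Backed
        by a flat capacity buffer so smaller batches reuse the same pages.
        """
        bufs = getattr(self, "_bufs", None)
        if bufs is None:
            bufs = self._bufs = {}
        n = int(np.prod(shape))
        flat = bufs.get(key)
        if flat is None or flat.size < n:
            flat = bufs[key] = np.empty(n, dtype=np.float32)
        buf = flat[:n].reshape(shape)
        if fill is not None:
            buf.fill(fill)
        return buf


class Conv2d(Layer):
    """Same-padded 2-D convolution (cross-correlation) with bias."""

    def __init__(self, in_ch, out_ch, kernel, stride=(1, 1), rng=None, name="conv"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kh, self.kw = kernel
        self.sh, self.sw = stride
        self.name = name
        self.needs_input_grad = True
        rng = rng or np.random.default_rng()
        fan_in = in_ch * self.kh * self.kw
        bound = 1.0 / np.sqrt(fan_in)
        self.w = rng.uniform(-bound, bound, (out_ch, in_ch, self.kh, self.kw)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(f"{self.name}.w", self.w, self.dw), (f"{self.name}.b", self.b, self.db)]

    def out_shape(self, shape):
        c, h, w = shape
        ho, _, _ = _same_pad(h, self.kh, self.sh)
        wo, _, _ = _same_pad(w, self.kw, self.sw)
        return (self.out_ch, ho, wo)

    def _wmat(self):
        # (out_ch, K) with K ordered (ki, kj, c), matching the im2col rows
        return np.ascontiguousarray(
            self.w.transpose(0, 2, 3, 1).reshape(self.out_ch, -1)
        )

    def _geometry(self, H, W):
        ho, pt, pb = _same_pad(H, self.kh, self.sh)
        wo, pl, pr = _same_pad(W, self.kw, self.sw)
        return (ho, wo), (pt, pb, pl, pr)

    def _im2col(self, xp, ho, wo):
        B, C = xp.shape[0], xp.shape[1]
        K = self.kh * self.kw * C
        cols = self._buffer("cols", (B, K, ho * wo))
        t = 0
        for ki in range(self.kh):
            for kj in range(self.kw):
                xs = xp[:, :, ki : ki + ho * self.sh : self.sh,
                        kj : kj + wo * self.sw : self.sw]
                cols[:, t : t + C, :] = xs.reshape(B, C, ho * wo)
                t += C
        return cols

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        (ho, wo), (pt, pb, pl, pr) = self._geometry(H, W)
        xp = self._buffer("xp", (B, C, H + pt + pb, W + pl + pr), fill=0.0)
        xp[:, :, pt : pt + H, pl : pl + W] = x
        cols = self._im2col(xp, ho, wo)
        out = np.matmul(self._wmat()[None], cols)  # (B, out_ch, ho*wo)
        out += self.b[None, :, None]
        self._cache = (cols if training else None, (B, C, H, W), (ho, wo), (pt, pl))
        return out.reshape(B, self.out_ch, ho, wo)

    def backward(self, grad):
        cols, (B, C, H, W), (ho, wo), (pt, pl) = self._cache
        gflat = grad.reshape(B, self.out_ch, ho * wo)
        # (out, P) @ (P, K) accumulated over the batch; cols[b].T is a view
        # BLAS consumes directly, so no large temporaries are formed
        dwmat = np.zeros((self.out_ch, cols.shape[1]), dtype=np.float32)
        for b in range(B):
            dwmat += gflat[b] @ cols[b].T
        self.dw[:] = dwmat.reshape(self.out_ch, self.kh, self.kw, C).transpose(
            0, 3, 1, 2
        )
        self.db[:] = gflat.sum(axis=(0, 2))
        self._cache = None
        if not self.needs_input_grad:
            return None
        _, (pt_, pb_, pl_, pr_) = self._geometry(H, W)
        dxp = self._buffer("dxp", (B, C, H + pt_ + pb_, W + pl_ + pr_), fill=0.0)
        for ki in range(self.kh):
            for kj in range(self.kw):
                wk = self.w[:, :, ki, kj]  # (out, C)
                dxs = np.matmul(wk.T[None], gflat)  # (B, C, P)
                dxp[:, :, ki : ki + ho * self.sh : self.sh,
                    kj : kj + wo * self.sw : self.sw] += dxs.reshape(B, C, ho, wo)
        return dxp[:, :, pt : pt + H, pl : pl + W]


class ReLU(Layer):
    def out_shape(self, shape):
        return shape

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class MaxPool2d(Layer):
    """Max pooling with ceil-mode output; pads with -inf as needed."""

    def __init__(self, kernel, stride):
        self.kh, self.kw = kernel
        self.sh, self.sw = stride

    def out_shape(self, shape):
        c, h, w = shape
        ho, _, _ = _same_pad(h, self.kh, self.sh)
        wo, _, _ = _same_pad(w, self.kw, self.sw)
        return (c, ho, wo)

    def _offset_view(self, xp, ki, kj, ho, wo):
        return xp[:, :, ki : ki + ho * self.sh : self.sh,
                  kj : kj + wo * self.sw : self.sw]

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        ho, pt, pb = _same_pad(H, self.kh, self.sh)
        wo, pl, pr = _same_pad(W, self.kw, self.sw)
        xp = self._buffer("xp", (B, C, H + pt + pb, W + pl + pr), fill=-np.inf)
        xp[:, :, pt : pt + H, pl : pl + W] = x
        out = self._buffer("out", (B, C, ho, wo), fill=-np.inf)
        for ki in range(self.kh):
            for kj in range(self.kw):
                np.maximum(out, self._offset_view(xp, ki, kj, ho, wo), out=out)
        self._cache = (xp, out, x.shape, (ho, wo), (pt, pl)) if training else None
        return out

    def backward(self, grad):
        xp, out, xshape, (ho, wo), (pt, pl) = self._cache
        B, C, H, W = xshape
        dxp = self._buffer("dxp", xp.shape, fill=0.0)
        unclaimed = np.ones(out.shape, dtype=bool)  # route ties to 1st match
        sel = np.empty(out.shape, dtype=bool)
        routed = np.empty(out.shape, dtype=np.float32)
        for ki in range(self.kh):
            for kj in range(self.kw):
                xs = self._offset_view(xp, ki, kj, ho, wo)
                np.equal(xs, out, out=sel)
                sel &= unclaimed
                np.multiply(grad, sel, out=routed)
                self._offset_view(dxp, ki, kj, ho, wo)[...] += routed
                unclaimed &= ~sel
        self._cache = None
        return dxp[:, :, pt : pt + H, pl : pl + W]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running inference statistics."""

    def __init__(self, ch, momentum=0.1, eps=1e-5, name="bnorm"):
        self.ch, self.momentum, self.eps, self.name = ch, momentum, eps, name
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def parameters(self):
        return [
            (f"{self.name}.gamma", self.gamma, self.dgamma),
            (f"{self.name}.beta", self.beta, self.dbeta),
        ]

    def out_shape(self, shape):
        return shape

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape, training)
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, grad):
        xhat, inv, shape, training = self._cache
        B, C, H, W = shape
        n = B * H * W
        self.dgamma[:] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[:] = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        if not training:
            return (g * inv[None, :, None, None]).astype(np.float32)
        dx = (inv[None, :, None, None] / n) * (
            n * g
            - g.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        return dx.astype(np.float32)


class GlobalAvgPool(Layer):
    def out_shape(self, shape):
        return (shape[0],)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (H * W), self._shape
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, name="fc"):
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(n_in)
        self.w = rng.uniform(-bound, bound, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.name = name

    def parameters(self):
        return [(f"{self.name}.w", self.w, self.dw), (f"{self.name}.b", self.b, self.db)]

    def out_shape(self, shape):
        return (self.w.shape[1],)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.w.T


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def out_shape(self, shape):
        for layer in self.layers:
            shape = layer.out_shape(shape)
        return shape

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                break
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    eps = 1e-12
    return float(-(onehot * np.log(probs + eps)).sum(axis=1).mean())
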