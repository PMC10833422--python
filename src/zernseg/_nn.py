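"""Minimal CPU neural-network engine (float32, manual backprop).

Layers are *functional*: ``forward`` returns ``(y, cache)`` and ``backward``
consumes that cache, so a layer's parameters can be shared across several
forward passes in one optimizer step (needed for the shared per-slice
encoder of the slice-context model).  Gradients accumulate into
``Param.grad``; call ``Adadelta.zero_grad()`` between steps.

Activations are channels-last ``(B, H, W, C)`` float32 — on a single CPU
this halves the transpose traffic of the usual channels-first layout.
Convolutions are 'same'-padded and computed as nine shifted GEMMs rather
than one big im2col, which avoids materializing the column matrix.  The
optimizer is Adadelta with the original settings (rho=0.95, eps=1e-6).
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2D(Layer):
    """k x k 'same' convolution; weights stored as (k, k, Cin, Cout)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.k = k
        self.W = Param(rng.standard_normal((k, k, cin, cout)) * scale)
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        k, p = self.k, self.k // 2
        B, H, Wd, C = x.shape
        cout = self.W.value.shape[-1]
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        else:
            xp = x
        y = np.empty((B, H, Wd, cout), dtype=F32)
        y[...] = self.b.value
        for i in range(k):
            for j in range(k):
                y += xp[:, i : i + H, j : j + Wd, :] @ self.W.value[i, j]
        return y, xp

    def backward(self, dy: np.ndarray, cache):
        xp = cache
        k, p = self.k, self.k // 2
        B, H, Wd, _ = dy.shape
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.b.grad += dy2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xw = xp[:, i : i + H, j : j + Wd, :].reshape(-1, xp.shape[-1])
                self.W.grad[i, j] += xw.T @ dy2
                dxp[:, i : i + H, j : j + Wd, :] += dy @ self.W.value[i, j].T
        return dxp[:, p : p + H, p : p + Wd, :] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        m = x > 0
        return x * m, m

    def backward(self, dy, cache):
        return dy * cache


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (H, W must be even)."""

    def forward(self, x):
        B, H, Wd, C = x.shape
        xr = x.reshape(B, H // 2, 2, Wd // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(B, H // 2, Wd // 2, C, 4)
        arg = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(y), (arg, x.shape)

    def backward(self, dy, cache):
        arg, xshape = cache
        B, H, Wd, C = xshape
        dxr = np.zeros((B, H // 2, Wd // 2, C, 4), dtype=F32)
        np.put_along_axis(dxr, arg[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(B, H // 2, Wd // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(B, H, Wd, C)


class ConvTranspose2(Layer):
    """2x2 transposed convolution, stride 2 (exact 2x upsampling).

    Weights stored as (2, 2, Cin, Cout).
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = Param(rng.standard_normal((2, 2, cin, cout)) * scale)
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        B, H, Wd, C = x.shape
        cout = self.W.value.shape[-1]
        y = np.empty((B, 2 * H, 2 * Wd, cout), dtype=F32)
        for a in range(2):
            for b in range(2):
                y[:, a::2, b::2, :] = x @ self.W.value[a, b]
        y += self.b.value
        return y, x

    def backward(self, dy, cache):
        x = cache
        x2 = x.reshape(-1, x.shape[-1])
        dx = np.zeros_like(x)
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        for a in range(2):
            for b in range(2):
                d = dy[:, a::2, b::2, :]
                self.W.grad[a, b] += x2.T @ d.reshape(-1, d.shape[-1])
                dx += d @ self.W.value[a, b].T
        return dx


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray, class_weights=None):
    """Mean cross-entropy over all pixels; returns ``(loss, dlogits, prob)``.

    ``logits``: (B, H, W, K); ``labels``: (B, H, W) integer codes.
    ``class_weights``: optional per-class vector; the loss becomes the
    weighted mean (weights normalized by their pixel-mean so the scale
    stays comparable to the unweighted loss).
    """
    p = softmax(logits, axis=-1)
    idx = labels[..., None].astype(np.int64)
    p_true = np.take_along_axis(p, idx, axis=-1)[..., 0]
    nll = -np.log(np.clip(p_true, 1e-7, 1.0))
    dlogits = p.copy()
    np.put_along_axis(dlogits, idx, np.take_along_axis(dlogits, idx, axis=-1) - 1.0, axis=-1)
    if class_weights is None:
        loss = float(nll.mean())
        dlogits /= labels.size
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
        wsum = w.sum()
        loss = float((w * nll).sum() / wsum)
        dlogits *= (w / wsum)[..., None]
    return loss, dlogits.astype(F32), p


class Adadelta:
    """Zeiler's Adadelta: per-parameter adaptive steps, no learning-rate tuning."""

    def __init__(self, params: list[Param], rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0):
        self.params = params
        self.rho, self.eps, self.lr = rho, eps, lr
        self.Eg = [np.zeros_like(p.value) for p in params]
        self.Ed = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        r, e = self.rho, self.eps
        for p, Eg, Ed in zip(self.params, self.Eg, self.Ed):
            Eg *= r
            Eg += (1 - r) * p.grad * p.grad
            delta = -np.sqrt(Ed + e) / np.sqrt(Eg + e) * p.grad
            Ed *= r
            Ed += (1 - r) * delta * delta
            p.value += self.lr * delta
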