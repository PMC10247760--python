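"""Minimal NumPy neural-network engine used by the U-Net segmenter.

Implements exactly the pieces the segmenter needs — 3x3 same-padding
convolutions, ReLU, 2x2 max pooling, nearest-neighbor upsampling, channel
concatenation, softmax, a soft multi-class DICE loss, and Adam — with manual
forward/backward passes.  Tensors are ``(batch, channels, height, width)``
float32 arrays.  All randomness flows through an explicit Generator, so runs
are bit-reproducible on one machine.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv3x3:
    """3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in, fan_out = in_ch * 9, out_ch * 9
        self.W = Param(xavier_uniform(rng, (out_ch, in_ch, 3, 3), fan_in, fan_out))
        self.b = Param(np.zeros(out_ch))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp
        y = np.zeros((n, h, w, self.W.value.shape[0]), dtype=DTYPE)
        for i in range(3):
            for j in range(3):
                # (n, c, h, w) x (o, c) -> (n, h, w, o)
                y += np.tensordot(xp[:, :, i:i + h, j:j + w], self.W.value[:, :, i, j],
                                  axes=([1], [1]))
        y += self.b.value
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, _, hp, wp = xp.shape
        h, w = hp - 2, wp - 2
        gyt = gy.transpose(0, 2, 3, 1)  # (n, h, w, o)
        self.b.grad += gyt.sum(axis=(0, 1, 2))
        gxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                patch = xp[:, :, i:i + h, j:j + w]  # (n, c, h, w)
                # dW: (o, c) = sum over n,h,w of gy * x
                self.W.grad[:, :, i, j] += np.tensordot(
                    gyt, patch, axes=([0, 1, 2], [0, 2, 3]))
                # dX: (n, h, w, c) = gy (n,h,w,o) x W (o,c)
                gxp[:, :, i:i + h, j:j + w] += np.tensordot(
                    gyt, self.W.value[:, :, i, j], axes=([3], [0])
                ).transpose(0, 3, 1, 2)
        self._xp = None
        return gxp[:, :, 1:-1, 1:-1]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0).astype(DTYPE)


class MaxPool2:
    """2x2 max pooling on even spatial dims; ties break to the first element."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = np.argmax(xr, axis=-1)
        return np.max(xr, axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(gxr, self._idx[..., None], gy[..., None], axis=-1)
        gx = gxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gx.reshape(n, c, h, w))


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dice_loss_with_grad(
    logits: np.ndarray, targets: np.ndarray, eps: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Soft DICE loss over per-class sigmoid heads, aggregated over the batch.

    ``logits`` has one channel per foreground class; ``targets`` is the
    matching stack of binary maps.  Each class contributes
    ``1 - (2*sum(s*t) + eps) / (sum(s) + sum(t) + eps)`` with ``s`` the
    sigmoid of its logit map; the loss is the mean over classes.  Treating
    the classes as independent binary problems (rather than one softmax)
    keeps a very thin class from being crushed by the gradient of an easy,
    much larger class sharing the same pixels' normalization.
    Returns (loss, gradient w.r.t. logits).
    """
    k = logits.shape[1]
    dlogits = np.zeros_like(logits, dtype=np.float64)
    losses = []
    for c in range(k):
        s = sigmoid(logits[:, c].astype(np.float64))
        t = targets[:, c]
        num = 2.0 * (s * t).sum() + eps
        den = s.sum() + t.sum() + eps
        losses.append(1.0 - num / den)
        dl_ds = -(2.0 * t * den - num) / (den * den) / k
        dlogits[:, c] = dl_ds * s * (1.0 - s)
    return float(np.mean(losses)), dlogits.astype(DTYPE)


class Adam:
    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m[...] = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v[...] = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)
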