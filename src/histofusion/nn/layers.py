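"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the fusion model needs: dense layers, ReLU, 2-D convolution
(im2col), 2x2 max pooling, flattening, and softmax cross-entropy.  Every
layer caches what its backward pass needs; parameters carry their own
gradient and momentum buffers so a plain momentum-SGD loop can drive them.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with gradient and momentum-velocity buffers."""

    __slots__ = ("value", "grad", "vel")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.vel = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Linear:
    """Affine layer y = x W + b with W of shape (in, out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        scale = scale if scale is not None else np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class Conv2d:
    """2-D convolution (NCHW) via im2col; supports stride and zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, pad: int = 0):
        fan_in = c_in * kernel * kernel
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(c_out, c_in, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        B, C, H, W = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Hp, Wp = x.shape[2], x.shape[3]
        Ho, Wo = (Hp - k) // s + 1, (Wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(
            x, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k)
        Wf = self.W.value.reshape(self.W.value.shape[0], -1)  # c_out, C*k*k
        out = cols @ Wf.T + self.b.value  # B, Ho*Wo, c_out
        self._cache = (cols, (B, C, H, W), (Hp, Wp), (Ho, Wo))
        return out.transpose(0, 2, 1).reshape(B, -1, Ho, Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W), (Hp, Wp), (Ho, Wo) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        c_out = dout.shape[1]
        dflat = dout.reshape(B, c_out, Ho * Wo).transpose(0, 2, 1)  # B,HW,c_out
        Wf = self.W.value.reshape(c_out, -1)
        self.W.grad += np.einsum("bnc,bnk->ck", dflat, cols).reshape(
            self.W.value.shape)
        self.b.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ Wf  # B, Ho*Wo, C*k*k
        dcols = dcols.reshape(B, Ho, Wo, C, k, k)
        dxp = np.zeros((B, C, Hp, Wp))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def params(self):
        return [self.W, self.b]


class MaxPool2:
    """2x2 max pooling with stride 2 (even input edges required)."""

    def __init__(self):
        self._cache = None

    def forward(self, x):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2 requires even spatial dims")
        r = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = r.max(axis=(3, 5))
        mask = r == out[:, :, :, None, :, None]
        # break ties toward the first max so gradients are not duplicated
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(B, C, H // 2, W // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5)
        self._cache = (mask, x.shape)
        return out

    def backward(self, dout):
        mask, (B, C, H, W) = self._cache
        dx = mask * dout[:, :, :, None, :, None]
        return dx.reshape(B, C, H, W)

    def params(self):
        return []


class Flatten:
    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
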