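"""Minimal 3D neural-network layers with explicit backpropagation.

A compact, self-contained CPU implementation sized for desk-scale training:
float32 tensors in ``(N, C, D, H, W)`` layout, im2col-style convolutions via
``sliding_window_view`` + ``tensordot``, and hand-derived backward passes
(verified against finite differences in the test suite).  Each layer caches
what its backward pass needs during forward; ``backward`` consumes that
cache and accumulates parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "DownConv",
    "UpConv",
    "BatchNorm3d",
    "PReLU",
    "Dropout",
    "Sigmoid",
    "Adam",
    "soft_dice",
    "soft_dice_loss_grad",
]


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def zero_grads(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Conv3d(Layer):
    """Same-padding 3D convolution with odd kernel size and stride 1.

    Computed as a zero-padded linear correlation via FFT: the input and the
    flipped kernel are transformed on a grid of at least ``n + k - 1`` per
    axis (no circular wrap in the retained region), multiplied per channel
    pair, and the 'same' window is cropped from the inverse transform.  The
    weight gradient reuses the cached input spectrum as a cross-correlation
    at the kernel lags.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("Conv3d requires an odd kernel")
        self.k = k
        self.pad = k // 2
        std = np.sqrt(2.0 / (cin * k**3))
        self.params["w"] = rng.normal(0.0, std, size=(cout, cin, k, k, k)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grads()
        self._xf: np.ndarray | None = None

    def _fft_shape(self, spatial):
        from scipy.fft import next_fast_len

        return tuple(next_fast_len(n + self.k - 1) for n in spatial)

    def forward(self, x, training=False):
        from scipy.fft import irfftn, rfftn

        p = self.pad
        spatial = x.shape[2:]
        fshape = self._fft_shape(spatial)
        xf = rfftn(x, fshape, axes=(2, 3, 4))
        self._xf = xf
        self._spatial = spatial
        wflip = np.flip(self.params["w"], axis=(2, 3, 4))
        wf = rfftn(wflip, fshape, axes=(2, 3, 4))
        yf = np.einsum("ncdhw,ocdhw->nodhw", xf, wf, optimize=True)
        full = irfftn(yf, fshape, axes=(2, 3, 4))
        sl = (slice(None), slice(None)) + tuple(slice(p, p + n) for n in spatial)
        y = full[sl].astype(np.float32)
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, gout):
        from scipy.fft import irfftn, rfftn

        k, p = self.k, self.pad
        spatial = self._spatial
        fshape = self._fft_shape(spatial)
        xf, self._xf = self._xf, None

        # pad gout so output lag 0 aligns with input position 0
        gp = np.zeros(gout.shape[:2] + fshape, dtype=np.float32)
        gsl = (slice(None), slice(None)) + tuple(slice(p, p + n) for n in spatial)
        gp[gsl] = gout
        gf = rfftn(gp, fshape, axes=(2, 3, 4))

        # weight gradient: cross-correlation of input and output grads at
        # kernel lags; circular wrap only affects lags beyond k-1
        ccf = np.einsum("ncdhw,nodhw->ocdhw", np.conj(xf), gf, optimize=True)
        cc = irfftn(ccf, fshape, axes=(2, 3, 4))
        lags = (k - 1) - np.arange(k)  # kernel offset dk lives at lag k-1-dk
        gw = cc[
            :,
            :,
            lags[:, None, None],
            lags[None, :, None],
            lags[None, None, :],
        ]
        self.grads["w"] += gw.astype(np.float32)
        self.grads["b"] += gout.sum(axis=(0, 2, 3, 4))

        # input gradient: convolution of gout with the unflipped kernel
        wf = rfftn(self.params["w"], fshape, axes=(2, 3, 4))
        gxf = np.einsum("nodhw,ocdhw->ncdhw", gf, wf, optimize=True)
        gxfull = irfftn(gxf, fshape, axes=(2, 3, 4))
        sl = (slice(None), slice(None)) + tuple(slice(2 * p, 2 * p + n) for n in spatial)
        return gxfull[sl].astype(np.float32)


class DownConv(Layer):
    """2x2x2 convolution with stride 2 (halves every spatial axis)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = np.sqrt(2.0 / (cin * 8))
        self.params["w"] = rng.normal(0.0, std, size=(cout, cin, 2, 2, 2)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grads()

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial shape {(d, h, w)} not divisible by 2")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        self._xr = xr
        y = np.einsum("ncdihjwl,ocijl->nodhw", xr, self.params["w"], optimize=True)
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, gout):
        xr = self._xr
        self._xr = None
        self.grads["w"] += np.einsum("nodhw,ncdihjwl->ocijl", gout, xr, optimize=True)
        self.grads["b"] += gout.sum(axis=(0, 2, 3, 4))
        gx = np.einsum("nodhw,ocijl->ncdihjwl", gout, self.params["w"], optimize=True)
        n, c = gx.shape[0], gx.shape[1]
        d, h, w = gx.shape[2] * 2, gx.shape[4] * 2, gx.shape[6] * 2
        return gx.reshape(n, c, d, h, w)


class UpConv(Layer):
    """2x2x2 transposed convolution with stride 2 (doubles every axis)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = np.sqrt(2.0 / (cin * 8))
        self.params["w"] = rng.normal(0.0, std, size=(cin, cout, 2, 2, 2)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grads()

    def forward(self, x, training=False):
        self._x = x
        y = np.einsum("ncdhw,coijl->nodihjwl", x, self.params["w"], optimize=True)
        n, o = y.shape[0], y.shape[1]
        d, h, w = x.shape[2] * 2, x.shape[3] * 2, x.shape[4] * 2
        return y.reshape(n, o, d, h, w) + self.params["b"][None, :, None, None, None]

    def backward(self, gout):
        x = self._x
        self._x = None
        n, o, d, h, w = gout.shape
        gr = gout.reshape(n, o, d // 2, 2, h // 2, 2, w // 2, 2)
        self.grads["w"] += np.einsum("nodihjwl,ncdhw->coijl", gr, x, optimize=True)
        self.grads["b"] += gout.sum(axis=(0, 2, 3, 4))
        return np.einsum("nodihjwl,coijl->ncdhw", gr, self.params["w"], optimize=True)


class BatchNorm3d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.zero_grads()
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * ivar[None, :, None, None, None]
        self._cache = (xhat, ivar, x.shape) if training else None
        self._xhat_eval = xhat if not training else None
        return self.params["gamma"][None, :, None, None, None] * xhat + self.params["beta"][
            None, :, None, None, None
        ]

    def backward(self, gout):
        axes = (0, 2, 3, 4)
        if self._cache is None:
            # eval-mode backward (fixed statistics): affine only
            xhat = self._xhat_eval
            self.grads["gamma"] += (gout * xhat).sum(axis=axes)
            self.grads["beta"] += gout.sum(axis=axes)
            ivar = 1.0 / np.sqrt(self.running_var + self.eps)
            return gout * (self.params["gamma"] * ivar)[None, :, None, None, None]
        xhat, ivar, shape = self._cache
        self._cache = None
        m = shape[0] * shape[2] * shape[3] * shape[4]
        self.grads["gamma"] += (gout * xhat).sum(axis=axes)
        self.grads["beta"] += gout.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None, None]
        sum_g = gout.sum(axis=axes)[None, :, None, None, None]
        sum_gx = (gout * xhat).sum(axis=axes)[None, :, None, None, None]
        return (g * ivar[None, :, None, None, None] / m) * (m * gout - sum_g - xhat * sum_gx)


class PReLU(Layer):
    """Parametric ReLU with one learned negative slope per channel."""

    def __init__(self, c: int, init: float = 0.25) -> None:
        super().__init__()
        self.params["a"] = np.full(c, init, dtype=np.float32)
        self.zero_grads()

    def forward(self, x, training=False):
        self._x = x
        a = self.params["a"][None, :, None, None, None]
        return np.where(x > 0, x, a * x)

    def backward(self, gout):
        x = self._x
        self._x = None
        a = self.params["a"][None, :, None, None, None]
        self.grads["a"] += (gout * np.minimum(x, 0)).sum(axis=(0, 2, 3, 4))
        return gout * np.where(x > 0, 1.0, a).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        mask, self._mask = self._mask, None
        return gout * mask


class Sigmoid(Layer):
    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, gout):
        y = self._y
        self._y = None
        return gout * y * (1.0 - y)


# ------------------------------------------------------------------ training

def soft_dice(pred: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Differentiable Dice with squared-sum denominator (training objective).

    ``2 * sum(p*t) / (sum(p^2) + sum(t^2))``; both-empty inputs give 1.
    The squared denominator makes the gradient vanish exactly at ``p == t``.
    """
    num = 2.0 * float((pred * target).sum()) + eps
    den = float((pred**2).sum() + (target**2).sum()) + eps
    return num / den


def soft_dice_loss_grad(pred: np.ndarray, target: np.ndarray, eps: float = 1e-7):
    """Loss ``1 - soft_dice`` and its gradient with respect to ``pred``."""
    num = 2.0 * (pred * target).sum() + eps
    den = (pred**2).sum() + (target**2).sum() + eps
    loss = 1.0 - num / den
    grad = -(2.0 * target * den - num * 2.0 * pred) / den**2
    return float(loss), grad.astype(np.float32)


class Adam:
    """Adam optimizer over a list of layers (beta1 is the momentum term)."""

    def __init__(self, layers, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bias1) / (np.sqrt(v[k] / bias2) + self.eps)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()
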