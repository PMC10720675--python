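"""Minimal NumPy convolutional-network engine.

Implements exactly the pieces the lymph-node segmentation models need:
2-D convolution (with dilation), ReLU/sigmoid, 2x2 max-pooling,
nearest-neighbour upsampling, additive attention gates, a combined
binary-cross-entropy + soft-Dice loss and an Adam optimizer.  Layout is
NCHW throughout; convolutions use zero 'same' padding so every layer
preserves spatial dimensions.

Backward passes are hand-derived and validated against finite
differences in the test suite.  The engine is single-threaded and meant
for desk-scale tile sizes (tens to a few hundred pixels), not GPU-scale
training.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "Upsample2",
    "AttentionGate",
    "DoubleConv",
    "MultiScaleConv",
    "Adam",
    "bce_dice_loss",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g.fill(0.0)


def _he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    """'Same'-padded 2-D convolution with optional dilation.

    A dilation rate r spaces the kernel taps r pixels apart, enlarging
    the receptive field of a k x k kernel to (k-1)*r + 1 without
    downsampling — the atrous convolution used by the multiscale U-Net.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dilation: int = 1):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.c_in, self.c_out, self.k, self.dilation = c_in, c_out, k, dilation
        self.W = Param(_he_normal(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, d = self.k, self.dilation
        p = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # cols: (N, C, k, k, H, W) gathered by shifted views
        cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, ki, kj] = xp[:, :, ki * d:ki * d + h, kj * d:kj * d + w]
        cols2 = cols.reshape(n, c * k * k, h * w)
        wmat = self.W.v.reshape(self.c_out, c * k * k)
        y = np.einsum("oc,ncp->nop", wmat, cols2, optimize=True)
        y += self.b.v[None, :, None]
        self._cache = (cols2, x.shape)
        return y.reshape(n, self.c_out, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols2, xshape = self._cache
        n, c, h, w = xshape
        k, d = self.k, self.dilation
        p = d * (k // 2)
        gy2 = gy.reshape(n, self.c_out, h * w)
        wmat = self.W.v.reshape(self.c_out, c * k * k)
        self.W.g += np.einsum("nop,ncp->oc", gy2, cols2, optimize=True).reshape(self.W.v.shape)
        self.b.g += gy2.sum(axis=(0, 2))
        gcols = np.einsum("oc,nop->ncp", wmat, gy2, optimize=True)
        gcols = gcols.reshape(n, c, k, k, h, w)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki * d:ki * d + h, kj * d:kj * d + w] += gcols[:, :, ki, kj]
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x):
        self._y = _sigmoid(x)
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MaxPool2:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even dimensions, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        idx, (n, c, h, w) = self._cache
        g = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(g, idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour x2 upsampling; backward sums over 2x2 blocks."""

    def params(self):
        return []

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class DoubleConv:
    """conv3x3-ReLU-conv3x3-ReLU, the standard U-Net block."""

    def __init__(self, c_in, c_out, rng):
        self.c1, self.r1 = Conv2d(c_in, c_out, 3, rng), ReLU()
        self.c2, self.r2 = Conv2d(c_out, c_out, 3, rng), ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, gy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(gy))))


class _AtrousUnit:
    """Parallel atrous 3x3 branches, concatenated then fused by a 1x1 conv.

    The branch at rate r sees the receptive field a plain 3x3 would see
    on an r-fold downsampled view, so rates (1, 2, 4) combine the fields
    of view of x10, x5 and x2.5 magnification in a single pass.
    """

    def __init__(self, c_in, c_out, rates, rng):
        self.branches = [Conv2d(c_in, c_out, 3, rng, dilation=r) for r in rates]
        self.brelu = [ReLU() for _ in rates]
        self.fuse = Conv2d(c_out * len(rates), c_out, 1, rng)
        self.frelu = ReLU()
        self.c_out = c_out

    def params(self):
        ps = []
        for b in self.branches:
            ps += b.params()
        return ps + self.fuse.params()

    def forward(self, x):
        outs = [r.forward(b.forward(x)) for b, r in zip(self.branches, self.brelu)]
        return self.frelu.forward(self.fuse.forward(np.concatenate(outs, axis=1)))

    def backward(self, gy):
        g = self.fuse.backward(self.frelu.backward(gy))
        gx = None
        c = self.c_out
        for i, (b, r) in enumerate(zip(self.branches, self.brelu)):
            gi = b.backward(r.backward(g[:, i * c:(i + 1) * c]))
            gx = gi if gx is None else gx + gi
        return gx


class MultiScaleConv:
    """Encoder block of the multiscale U-Net: two stacked atrous units."""

    def __init__(self, c_in, c_out, rates, rng):
        self.u1 = _AtrousUnit(c_in, c_out, rates, rng)
        self.u2 = _AtrousUnit(c_out, c_out, rates, rng)

    def params(self):
        return self.u1.params() + self.u2.params()

    def forward(self, x):
        return self.u2.forward(self.u1.forward(x))

    def backward(self, gy):
        return self.u1.backward(self.u2.backward(gy))


class AttentionGate:
    """Additive attention gate on a skip connection.

    The decoder feature g ("gating signal") and the encoder skip x are
    projected to an intermediate width, summed, squashed, and reduced to
    a per-pixel weight in [0, 1] that rescales the skip.
    """

    def __init__(self, c_x, c_g, c_int, rng):
        self.wx = Conv2d(c_x, c_int, 1, rng)
        self.wg = Conv2d(c_g, c_int, 1, rng)
        self.relu = ReLU()
        self.psi = Conv2d(c_int, 1, 1, rng)
        self.sig = Sigmoid()
        self._cache = None

    def params(self):
        return self.wx.params() + self.wg.params() + self.psi.params()

    def forward(self, x, g):
        a = self.relu.forward(self.wx.forward(x) + self.wg.forward(g))
        p = self.sig.forward(self.psi.forward(a))
        self._cache = (x, p)
        return x * p

    def backward(self, gy):
        x, p = self._cache
        gx_direct = gy * p
        gp = (gy * x).sum(axis=1, keepdims=True)
        ga = self.psi.backward(self.sig.backward(gp))
        ga = self.relu.backward(ga)
        gx = gx_direct + self.wx.backward(ga)
        gg = self.wg.backward(ga)
        return gx, gg


def bce_dice_loss(logits: np.ndarray, target: np.ndarray,
                  valid: np.ndarray | None = None,
                  mode: str = "bce_plus_dice", smooth: float = 1.0):
    """Binary cross-entropy plus soft-Dice loss on logits.

    Parameters
    ----------
    logits, target : arrays of identical shape; target in {0, 1}.
    valid : optional boolean mask; False pixels (e.g. zero-padding of an
        undersized tile) contribute neither to the loss nor the gradient.
    mode : 'bce', 'dice' or 'bce_plus_dice' (equal weights).

    Returns ``(loss, grad_wrt_logits)``.
    """
    t = target.astype(np.float64)
    v = np.ones_like(t) if valid is None else valid.astype(np.float64)
    nv = max(v.sum(), 1.0)
    p = _sigmoid(logits)
    # stable BCE on logits: max(z,0) - z*t + log(1+exp(-|z|))
    z = logits
    bce = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))) * v
    bce_loss = bce.sum() / nv
    g_bce = (p - t) * v / nv

    inter = (p * t * v).sum()
    denom = ((p + t) * v).sum()
    dice = (2.0 * inter + smooth) / (denom + smooth)
    dice_loss = 1.0 - dice
    # d(dice)/dp_i = (2 t_i (denom+s) - (2 inter + s)) / (denom+s)^2
    g_dice_p = -(2.0 * t * (denom + smooth) - (2.0 * inter + smooth)) / (denom + smooth) ** 2
    g_dice = g_dice_p * p * (1.0 - p) * v

    if mode == "bce":
        return bce_loss, g_bce
    if mode == "dice":
        return dice_loss, g_dice
    if mode == "bce_plus_dice":
        return bce_loss + dice_loss, g_bce + g_dice
    raise ValueError(f"unknown loss mode {mode!r}")


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.u = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, u in zip(self.params, self.m, self.u):
            m *= self.b1
            m += (1 - self.b1) * p.g
            u *= self.b2
            u += (1 - self.b2) * p.g ** 2
            p.v -= self.lr * (m / b1t) / (np.sqrt(u / b2t) + self.eps)
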