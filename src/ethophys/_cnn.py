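"""Minimal convolutional network in numpy (single-threaded, deterministic).

Just enough machinery for the desk-scale heatmap regressor: stride-1
"same" convolutions via im2col, 2×2 max pooling, ReLU, sigmoid output,
weighted pixelwise binary cross-entropy (or a focal variant), and Adam.
Everything runs on CPU and is exactly reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv2d:
    """Stride-1 same-padding convolution."""

    def __init__(self, c_in, c_out, k, rng):
        fan_in = c_in * k * k
        self.W = rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.k = k
        self.p = k // 2

    def forward(self, x):
        n, c, h, w = x.shape
        k, p = self.k, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ wmat.T + self.b
        self._cols, self._shape = cols, (n, c, h, w)
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, dout):
        n, c, h, w = self._shape
        k, p = self.k, self.p
        c_out = dout.shape[1]
        dflat = dout.reshape(n, c_out, h * w).transpose(0, 2, 1)  # n,hw,cout
        wmat = self.W.reshape(c_out, -1)
        self.dW = np.einsum("npo,npk->ok", dflat, self._cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=(0, 1))
        dcols = dflat @ wmat  # n, hw, c*k*k
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2×2, stride-2 max pooling (even spatial dims assumed)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = dout[:, :, :, None, :, None] * self._mask
        return d.reshape(n, c, h, w)


class HeatmapNet:
    """conv–pool–conv–pool–conv heatmap regressor at output stride 4."""

    def __init__(self, n_classes, channels=(8, 16), kernel=5, seed=0):
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        self.layers = [
            Conv2d(1, c1, kernel, rng), ReLU(), MaxPool2(),
            Conv2d(c1, c2, kernel, rng), ReLU(), MaxPool2(),
            Conv2d(c2, n_classes, 3, rng),
        ]
        self.n_classes = n_classes
        self.stride = 4

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        self._logits = x
        return 1.0 / (1.0 + np.exp(-x))

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def conv_layers(self):
        return [l for l in self.layers if isinstance(l, Conv2d)]


def bce_loss_grad(p, y, pos_weight=1.0, focal_gamma=None):
    """Weighted soft-target BCE (optionally focal): loss and dL/dlogit.

    Positive (target) pixels get weight ``pos_weight``; with soft targets
    the per-pixel weight is 1 + (pos_weight−1)·y.  The returned gradient is
    with respect to the pre-sigmoid logits, averaged over all pixels.
    """
    eps = 1e-7
    p = np.clip(p, eps, 1 - eps)
    w = 1.0 + (pos_weight - 1.0) * y
    if focal_gamma is not None:
        mod = y * (1 - p) ** focal_gamma + (1 - y) * p**focal_gamma
        w = w * mod
    loss = -(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).mean()
    # exact gradient for the non-focal case; for focal we use the same
    # leading term (standard practice: modulating factor treated as weight)
    grad = (w * (p - y)) / p.size
    return loss, grad


class Adam:
    def __init__(self, net, lr=3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.net.conv_layers()):
            for name, grad in (("W", layer.dW), ("b", layer.db)):
                key = (li, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(grad)
                    self.v[key] = np.zeros_like(grad)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad**2
                mh = self.m[key] / (1 - self.b1**self.t)
                vh = self.v[key] / (1 - self.b2**self.t)
                update = self.lr * mh / (np.sqrt(vh) + self.eps)
                setattr(layer, name, getattr(layer, name) - update)
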