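"""Minimal CNN building blocks on numpy with explicit forward/backward.

Activations are NCHW arrays (float32 in ordinary training; the layers
preserve whatever dtype they are fed).  Each layer caches what its backward
pass needs; ``backward`` consumes the upstream gradient and returns the
input gradient, accumulating parameter gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ConvTranspose2x2", "MaxPool2x2", "ReLU", "Dropout",
           "softmax_cross_entropy", "Adam"]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3×3 (or 1×1) convolution, stride 1, 'same' zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.k = kernel
        fan_in = in_ch * kernel * kernel
        # He-normal init for ReLU nets
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, kernel, kernel))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(out_ch, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}

    def forward(self, x, training=False):
        self._x = x
        W, b = self.params["W"], self.params["b"]
        if self.k == 1:
            # 1×1 conv is a channel-mixing matmul
            y = np.einsum("nchw,dc->ndhw", x, W[:, :, 0, 0], optimize=True)
            return y + b[None, :, None, None]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
        y = np.tensordot(cols, W, axes=([1, 4, 5], [1, 2, 3]))  # N,H,W,D
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        return y + b[None, :, None, None]

    def backward(self, dy):
        x, W = self._x, self.params["W"]
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        if self.k == 1:
            self.grads["W"][:, :, 0, 0] += np.einsum(
                "nchw,ndhw->dc", x, dy, optimize=True)
            return np.einsum("ndhw,dc->nchw", dy, W[:, :, 0, 0], optimize=True)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
        # dW[d,c,a,b] = sum_{n,h,w} x_cols[n,c,h,w,a,b] * dy[n,d,h,w]
        dW = np.tensordot(dy, cols, axes=([0, 2, 3], [0, 2, 3]))  # D,C,3,3
        self.grads["W"] += dW
        # dX = 'full' correlation of dy with W flipped
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dcols = sliding_window_view(dyp, (3, 3), axis=(2, 3))  # N,D,H,W,3,3
        Wr = W[:, :, ::-1, ::-1]
        dx = np.tensordot(dcols, Wr, axes=([1, 4, 5], [0, 2, 3]))  # N,H,W,C
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ConvTranspose2x2(Layer):
    """2×2 transposed convolution with stride 2 (learned 2× upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * 4
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_ch, out_ch, 2, 2))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(out_ch, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}

    def forward(self, x, training=False):
        self._x = x
        N, C, H, Wd = x.shape
        W = self.params["W"]
        y6 = np.einsum("ncij,cdab->ndiajb", x, W, optimize=True)
        y = y6.reshape(N, W.shape[1], 2 * H, 2 * Wd)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        x = self._x
        N, C, H, Wd = x.shape
        D = self.params["W"].shape[1]
        # dy as ndiajb: reshape (N,D,2H,2W) -> (N,D,H,2,W,2)
        dy6 = dy.reshape(N, D, H, 2, Wd, 2)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        self.grads["W"] += np.einsum("ncij,ndiajb->cdab", x, dy6, optimize=True)
        return np.einsum("ndiajb,cdab->ncij", dy6, self.params["W"], optimize=True)


class MaxPool2x2(Layer):
    def __init__(self):
        super().__init__()

    def forward(self, x, training=False):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        y = xr.max(axis=(3, 5))
        # distribute gradient evenly over tied maxima
        mask = xr == y[:, :, :, None, :, None]
        self._mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        self._shape = x.shape
        return y

    def backward(self, dy):
        g = self._mask * dy[:, :, :, None, :, None]
        return g.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, dy):
        return np.where(self._pos, dy, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          class_weights: np.ndarray | None = None):
    """Per-pixel softmax + categorical cross-entropy.

    Parameters
    ----------
    logits : (N, K, H, W) float
    targets : (N, H, W) int in [0, K)

    Returns
    -------
    loss : float (mean over all pixels)
    probs : (N, K, H, W)
    grad : d loss / d logits, same shape as logits
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    N, K, H, W = probs.shape
    idx_n, idx_h, idx_w = np.ogrid[:N, :H, :W]
    p_true = probs[idx_n, targets, idx_h, idx_w]
    if class_weights is None:
        w = 1.0
        norm = N * H * W
    else:
        cw = np.asarray(class_weights, dtype=np.float64)
        w = cw[targets]
        norm = float(w.sum())
    loss = float(np.sum(w * -np.log(np.maximum(p_true, 1e-12))) / norm)
    onehot = np.zeros_like(probs)
    onehot[idx_n, targets, idx_h, idx_w] = 1.0
    if class_weights is None:
        grad = (probs - onehot) / norm
    else:
        grad = (probs - onehot) * w[:, None, :, :] / norm
    return loss, probs, grad.astype(logits.dtype)


class Adam:
    """Adaptive-moment estimation over a list of layers' parameters."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()}
                  for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()}
                  for ly in self.layers]

    def zero_grad(self):
        for ly in self.layers:
            for g in ly.grads.values():
                g.fill(0.0)

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= (self.lr * (m[k] / bc1)
                      / (np.sqrt(v[k] / bc2) + self.eps)).astype(p.dtype)
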