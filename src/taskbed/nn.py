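"""Minimal convolutional-network engine (numpy, CPU).

Implements exactly the layers the denoiser and the appended observers need:
3x3 same-padding convolution, per-channel batch normalization, ReLU, and an
Adam optimizer, with manual reverse-mode gradients. Activations use the
layout ``(C, B, H, W)`` (channel leading, batch folded into the spatial
GEMM dimension), so each convolution is a single
``(c_out, c_in*k*k) @ (c_in*k*k, B*H*W)`` matrix product; the input
gradient of a stride-1 same-padded convolution is the convolution of the
output gradient with the spatially flipped kernels, so no scatter (col2im)
is needed anywhere. All arrays are float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(C, B, H, W) -> (C*k*k, B*H*W) patches with same-size zero padding.

    Built from k*k shifted slabs of the padded input; the row ordering
    (channel-major, then kernel offset) matches the (c_out, c_in*k*k)
    weight layout.
    """
    C, B, H, W = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.empty((C, k * k, B, H, W), dtype=x.dtype)
    j = 0
    for dr in range(k):
        for dc in range(k):
            out[:, j] = xp[:, :, dr : dr + H, dc : dc + W]
            j += 1
    return out.reshape(C * k * k, B * H * W)


class Conv2d:
    """3x3 (or kxk) stride-1 same-padding convolution."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.W = (rng.standard_normal((c_out, fan_in)) * std).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, need_grad: bool) -> np.ndarray:
        C, B, H, W = x.shape
        cols = im2col(x, self.k)
        if need_grad:
            self._cache = (cols, (C, B, H, W))
        out = self.W @ cols
        out += self.b[:, None]
        return out.reshape(self.c_out, B, H, W)

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        cols, (C, B, H, W) = self._cache
        dm = dout.reshape(self.c_out, B * H * W)
        self.grads["W"] = (dm @ cols.T).astype(DTYPE)
        self.grads["b"] = dm.sum(axis=1).astype(DTYPE)
        self._cache = None
        if not need_dx:
            return None
        Wk = self.W.reshape(self.c_out, self.c_in, self.k, self.k)
        Wf = np.ascontiguousarray(
            Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        ).reshape(self.c_in, self.c_out * self.k * self.k)
        cols_d = im2col(dout, self.k)
        return (Wf @ cols_d).reshape(self.c_in, B, H, W)


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, train: bool, need_grad: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None, None]) / std[:, None, None, None]
        if need_grad:
            self._cache = (xhat, std, train)
        return (self.gamma[:, None, None, None] * xhat
                + self.beta[:, None, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, train = self._cache
        self._cache = None
        self.grads["gamma"] = (dout * xhat).sum(axis=(1, 2, 3)).astype(DTYPE)
        self.grads["beta"] = dout.sum(axis=(1, 2, 3)).astype(DTYPE)
        dxhat = dout * self.gamma[:, None, None, None]
        if not train:
            # frozen statistics: normalization is a fixed affine map
            return dxhat / std[:, None, None, None]
        m = dxhat.mean(axis=(1, 2, 3))[:, None, None, None]
        mx = (dxhat * xhat).mean(axis=(1, 2, 3))[:, None, None, None]
        return (dxhat - m - xhat * mx) / std[:, None, None, None]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, need_grad: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if need_grad:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dout * mask


class Adam:
    """Adam optimizer over named parameter tensors (updated in place)."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named: list[tuple[str, np.ndarray, np.ndarray]]) -> None:
        """``named`` is a list of (key, param, grad); params mutated in place."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for key, p, g in named:
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= (self.lr * (m / corr1)
                  / (np.sqrt(v / corr2) + self.eps)).astype(p.dtype)


def balanced_batches(labels: np.ndarray, batch_size: int,
                     rng: np.random.Generator):
    """Yield index arrays with equal numbers of present/absent images.

    The number of batches per epoch is set by the smaller class; within a
    batch, half the slots come from each class.
    """
    present = np.flatnonzero(labels > 0)
    absent = np.flatnonzero(labels == 0)
    half = batch_size // 2
    rng.shuffle(present)
    rng.shuffle(absent)
    n_batches = min(len(present), len(absent)) // half
    for k in range(n_batches):
        idx = np.concatenate([
            present[k * half : (k + 1) * half],
            absent[k * half : (k + 1) * half],
        ])
        yield idx
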