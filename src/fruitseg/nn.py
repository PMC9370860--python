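"""Minimal CPU neural-network layers with explicit backprop.

The segmentation networks in this package are small enough that a direct
numpy implementation (im2col convolutions, float32, Adam) trains in
seconds on one core. Layers cache what their backward pass needs; the
network graphs in :mod:`fruitseg.segnet` call ``forward``/``backward``
explicitly in reverse order.

Tensors are NCHW float32 throughout.
"""

from __future__ import annotations

import numpy as np


class Conv2d:
    """2-D convolution with stride, dilation and "same" zero padding.

    ``same`` here means output size ``ceil(H / stride)`` for odd kernels,
    the usual choice for stride-2 encoders.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.dilation = kernel, stride, dilation
        self.pad = dilation * (kernel - 1) // 2
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        # He initialization for ReLU networks
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [("W", self), ("b", self)]

    def _out_size(self, size: int) -> int:
        eff = self.dilation * (self.k - 1) + 1
        return (size + 2 * self.pad - eff) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self._out_size(h), self._out_size(w)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = np.empty((n, c, self.k * self.k, oh * ow), dtype=np.float32)
        for idx in range(self.k * self.k):
            di = (idx // self.k) * self.dilation
            dj = (idx % self.k) * self.dilation
            patch = xp[
                :, :, di : di + self.stride * oh : self.stride,
                dj : dj + self.stride * ow : self.stride,
            ]
            cols[:, :, idx, :] = patch.reshape(n, c, oh * ow)
        cols = cols.reshape(n, c * self.k * self.k, oh * ow)
        out = np.einsum("of,nfl->nol", self.W, cols, optimize=True)
        out += self.b[None, :, None]
        self._cache = (cols, x.shape, (oh, ow))
        return out.reshape(n, self.out_ch, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, (oh, ow) = self._cache
        n, c, h, w = x_shape
        g = grad.reshape(n, self.out_ch, oh * ow)
        self.dW += np.einsum("nol,nfl->of", g, cols, optimize=True)
        self.db += g.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", self.W, g, optimize=True)
        dcols = dcols.reshape(n, c, self.k * self.k, oh * ow)
        p = self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for idx in range(self.k * self.k):
            di = (idx // self.k) * self.dilation
            dj = (idx % self.k) * self.dilation
            dxp[
                :, :, di : di + self.stride * oh : self.stride,
                dj : dj + self.stride * ow : self.stride,
            ] += dcols[:, :, idx, :].reshape(n, c, oh, ow)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-centred sampling)."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        pos = (o + 0.5) * scale - 0.5
        pos = min(max(pos, 0.0), n_in - 1.0)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n_in - 1)
        t = pos - lo
        A[o, lo] += 1.0 - t
        A[o, hi] += t
    return A


class BilinearUpsample:
    """Separable bilinear resize expressed as two matrix products.

    ``y = A x B^T`` per channel, so the backward pass is the exact
    transpose ``A^T g B``.
    """

    def __init__(self, out_hw: tuple[int, int]):
        self.out_hw = out_hw
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def _get(self, in_hw):
        key = (in_hw, tuple(self.out_hw))
        if key not in self._mats:
            self._mats[key] = (
                _interp_matrix(self.out_hw[0], in_hw[0]),
                _interp_matrix(self.out_hw[1], in_hw[1]),
            )
        return self._mats[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_hw = x.shape[2:]
        A, B = self._get(self._in_hw)
        tmp = np.einsum("oh,nchw->ncow", A, x, optimize=True)
        return np.einsum("pw,ncow->ncop", B, tmp, optimize=True)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        A, B = self._get(self._in_hw)
        tmp = np.einsum("pw,ncop->ncow", B, grad, optimize=True)
        return np.einsum("oh,ncow->nchw", A, tmp, optimize=True)


def softmax_cross_entropy(
    logits: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-pixel 2-class cross-entropy and its gradient w.r.t. logits.

    ``logits``: (N, 2, H, W); ``target``: (N, H, W) integer class ids.
    """
    n, c, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = (
        np.arange(n)[:, None, None],
        target,
        np.arange(h)[None, :, None],
        np.arange(w)[None, None, :],
    )
    eps = 1e-12
    loss = float(-np.log(p[idx[0], target, idx[2], idx[3]] + eps).mean())
    grad = p.copy()
    onehot = np.zeros_like(p)
    onehot[idx[0], target, idx[2], idx[3]] = 1.0
    grad = (grad - onehot) / (n * h * w)
    return loss, grad.astype(np.float32)


class Adam:
    """Adam over an explicit list of (layer, attr) parameter slots."""

    def __init__(self, slots, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = list(slots)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(layer, name)) for name, layer in self.slots]
        self.v = [np.zeros_like(getattr(layer, name)) for name, layer in self.slots]

    def zero_grad(self):
        for name, layer in self.slots:
            getattr(layer, "d" + name).fill(0.0)

    def step(self):
        self.t += 1
        for i, (name, layer) in enumerate(self.slots):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(layer, name)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
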