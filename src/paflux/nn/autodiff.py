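"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the surrogate architectures
need: broadcast arithmetic, reductions, 2-D convolution (stride 1), 2x2
max-pooling, nearest-neighbour upsampling, batch normalization, channel
concatenation, leaky-rectifier / Gaussian-error activations, dropout and
the mode-truncated spectral convolution. Gradients are accumulated by a
topological backward sweep; every primitive's adjoint is covered by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.fft
from scipy.special import erf

__all__ = ["Tensor", "concat", "conv2d", "maxpool2", "upsample2",
           "batchnorm2d", "leaky_relu", "gelu", "dropout", "spectral_conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def _backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = _backward
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def sqrt(self):
        return self**0.5

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"


# -- structural ops -------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = _backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) in NCHW layout.

    Computed as a sum of kernel-offset 1x1 matmuls in channel-major
    layout, which keeps every matmul dense and avoids im2col copies.
    """
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = xp.shape[2] - kh + 1
    wo = xp.shape[3] - kw + 1
    xp_t = np.ascontiguousarray(xp.transpose(1, 0, 2, 3))  # (c, n, hp, wp)
    acc = np.zeros((o, n * ho * wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = xp_t[:, :, i:i + ho, j:j + wo].reshape(c, -1)
            acc += weight.data[:, :, i, j] @ sl
    y = acc.reshape(o, n, ho, wo).transpose(1, 0, 2, 3)
    if bias is not None:
        y += bias.data.reshape(1, o, 1, 1)
        parents = (x, weight, bias)
    else:
        parents = (x, weight)
    out = Tensor(y, _parents=parents)

    def _backward(g):
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, -1)
        gw = np.empty_like(weight.data)
        need_gx = x.requires_grad or x._parents
        gxp_t = np.zeros_like(xp_t) if need_gx else None
        for i in range(kh):
            for j in range(kw):
                sl = xp_t[:, :, i:i + ho, j:j + wo].reshape(c, -1)
                gw[:, :, i, j] = gm @ sl.T
                if need_gx:
                    gxp_t[:, :, i:i + ho, j:j + wo] += (
                        weight.data[:, :, i, j].T @ gm
                    ).reshape(c, n, ho, wo)
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if need_gx:
            gxp = gxp_t.transpose(1, 0, 2, 3)
            x._accumulate(np.ascontiguousarray(
                gxp[:, :, p:p + h, p:p + w] if p else gxp
            ))

    out._backward = _backward
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(v).reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, _parents=(x,))

    def _backward(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = gv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(np.ascontiguousarray(gx).reshape(n, c, h, w))

    out._backward = _backward
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(y, _parents=(x,))
    n, c, h, w = x.data.shape

    def _backward(g):
        gx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accumulate(gx)

    out._backward = _backward
    return out


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, negative_slope * x.data), _parents=(x,))
    out._backward = lambda g: x._accumulate(
        np.where(pos, g, negative_slope * g)
    )
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error linear unit: x * Phi(x)."""
    cdf = 0.5 * (1.0 + erf(x.data / np.sqrt(2.0)))
    out = Tensor(x.data * cdf, _parents=(x,))

    def _backward(g):
        pdf = np.exp(-0.5 * x.data**2) / np.sqrt(2.0 * np.pi)
        x._accumulate(g * (cdf + x.data * pdf))

    out._backward = _backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p == 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = Tensor(x.data * mask, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    cshape = (1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(cshape)) * invstd.reshape(cshape)
        out = Tensor(gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape),
                     _parents=(x, gamma, beta))

        def _backward(g):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                ghat = g * gamma.data.reshape(cshape)
                m1 = ghat.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (ghat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = invstd.reshape(cshape) * (ghat - m1 - xhat * m2)
                x._accumulate(gx)

        out._backward = _backward
        return out

    invstd = 1.0 / np.sqrt(running_var + eps)
    scale = gamma.data * invstd
    shift = beta.data - running_mean * scale
    out = Tensor(x.data * scale.reshape(cshape) + shift.reshape(cshape),
                 _parents=(x, gamma, beta))
    xhat_eval = (x.data - running_mean.reshape(cshape)) * invstd.reshape(cshape)

    def _backward(g):
        gamma._accumulate((g * xhat_eval).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            x._accumulate(g * scale.reshape(cshape))

    out._backward = _backward
    return out


def _mode_indices(n: int, modes: int) -> np.ndarray:
    """Symmetric retained-frequency index set {k : |k| < modes} of size 2m-1."""
    if 2 * modes - 1 > n:
        raise ValueError(f"{modes} modes exceed the Nyquist limit of a {n}-point axis")
    return np.concatenate([np.arange(modes), np.arange(n - modes + 1, n)])


def spectral_conv2d(x: Tensor, w_real: Tensor, w_imag: Tensor,
                    modes: int) -> Tensor:
    """Mode-truncated spectral convolution.

    Fourier-transforms the latent field, multiplies the retained low
    frequencies (|k| < modes per axis) by learnable complex weights of
    shape (C_in, C_out, 2m-1, 2m-1), zeroes everything else, and returns
    the real part of the inverse transform. The retained index set is
    computed per input size, so one weight tensor serves any resolution
    with at least 2m-1 samples per axis.
    """
    n, cin, h, w = x.data.shape
    kz = _mode_indices(h, modes)
    kx = _mode_indices(w, modes)
    sel = np.ix_(kz, kx)
    X = scipy.fft.fft2(x.data, axes=(2, 3))
    Xs = X[:, :, sel[0], sel[1]]  # (n, cin, M, M)
    W = w_real.data + 1j * w_imag.data  # (cin, cout, M, M)
    Ys = np.einsum("nimk,iomk->nomk", Xs, W)
    cout = W.shape[1]
    cdtype = np.complex64 if x.data.dtype == np.float32 else np.complex128
    out_ft = np.zeros((n, cout, h, w), dtype=cdtype)
    out_ft[:, :, sel[0], sel[1]] = Ys
    y = scipy.fft.ifft2(out_ft, axes=(2, 3)).real.astype(x.data.dtype)
    out = Tensor(y, _parents=(x, w_real, w_imag))

    def _backward(g):
        G = scipy.fft.fft2(g, axes=(2, 3))
        Gs = G[:, :, sel[0], sel[1]]  # (n, cout, M, M)
        cw = np.einsum("nimk,nomk->iomk", np.conj(Xs), Gs) / (h * w)
        w_real._accumulate(cw.real.astype(w_real.data.dtype))
        w_imag._accumulate(cw.imag.astype(w_imag.data.dtype))
        if x.requires_grad or x._parents:
            gx_ft = np.zeros((n, cin, h, w), dtype=X.dtype)
            gx_ft[:, :, sel[0], sel[1]] = np.einsum(
                "nomk,iomk->nimk", Gs, np.conj(W)
            )
            x._accumulate(scipy.fft.ifft2(gx_ft, axes=(2, 3)).real.astype(x.data.dtype))

    out._backward = _backward
    return out
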