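"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the 1-D convolutional GAN needs: broadcast
arithmetic, matmul, strided 1-D convolution / transposed convolution,
reductions, element-wise nonlinearities, concatenation, masking, and the
magnitude of an n-point FFT.  Gradients are accumulated in float64.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "conv_transpose1d",
    "fft_magnitude",
    "instance_norm",
    "prelu",
    "leaky_relu",
    "precision",
]

DTYPE = np.float64


@contextmanager
def precision(dtype):
    """Temporarily change the dtype new Tensors are created with.

    Training uses float32 for speed; the default float64 keeps the loss
    functions bit-comparable with reference formula implementations.
    """
    global DTYPE
    prev = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError(f"item() requires a single-element tensor, got {self.data.shape}")
        return float(self.data.reshape(()))

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution is adopted without copying; later contributions
        # allocate a fresh array (never write in place: g may alias a buffer
        # shared with another node)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return self._make(self.data[key], (self,), backward)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- element-wise nonlinearities -------------------------------------

    def relu(self):
        pos = self.data > 0

        def backward(g):
            self._accumulate(g * pos)

        return self._make(self.data * pos, (self,), backward)

    def abs(self):
        s = np.sign(self.data)

        def backward(g):
            self._accumulate(g * s)

        return self._make(np.abs(self.data), (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - y**2))

        return self._make(y, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accumulate(g * y * (1.0 - y))

        return self._make(y, (self,), backward)

    def sqrt(self):
        y = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / y)

        return self._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(g):
            self._accumulate(g * y)

        return self._make(y, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) slice over the temporal axis."""
    mu = x.data.mean(axis=2, keepdims=True)
    centered = x.data - mu
    var = (centered * centered).mean(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = centered * inv

    def backward(g):
        gm = g.mean(axis=2, keepdims=True)
        gym = (g * y).mean(axis=2, keepdims=True)
        x._accumulate((g - gm - y * gym) * inv)

    return x._make(y, (x,), backward)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """max(x, 0) + slope * min(x, 0) with a learnable per-channel slope (1, C, 1)."""
    pos = x.data > 0
    neg = np.minimum(x.data, 0)
    y = np.where(pos, x.data, slope.data * neg)

    def backward(g):
        x._accumulate(np.where(pos, g, slope.data * g))
        slope._accumulate((g * neg).sum(axis=(0, 2), keepdims=True))

    return x._make(y, (x, slope), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    pos = x.data > 0
    y = np.where(pos, x.data, slope * x.data)

    def backward(g):
        x._accumulate(np.where(pos, g, slope * g))

    return x._make(y, (x,), backward)


def _im2col(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """View of padded input with shape (B, C, L_out, K)."""
    b, c, lp = xp.shape
    l_out = (lp - kernel) // stride + 1
    sb, sc, sl = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (b, c, l_out, kernel), (sb, sc, sl * stride, sl), writeable=False
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int, padding: int) -> Tensor:
    """x (B, C_in, L) * w (C_out, C_in, K) + b (C_out,) -> (B, C_out, L_out)."""
    kernel = w.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    cols = _im2col(xp, kernel, stride)
    out = np.einsum("bclk,ock->bol", cols, w.data, optimize=True)
    out += b.data[None, :, None]

    def backward(g):
        w._accumulate(np.einsum("bol,bclk->ock", g, cols, optimize=True))
        b._accumulate(g.sum(axis=(0, 2)))
        dcols = np.einsum("bol,ock->bclk", g, w.data, optimize=True)
        dxp = np.zeros_like(xp)
        l_out = g.shape[2]
        for k in range(kernel):
            dxp[:, :, k : k + l_out * stride : stride] += dcols[:, :, :, k]
        dx = dxp[:, :, padding : dxp.shape[2] - padding] if padding else dxp
        x._accumulate(dx)

    return x._make(out, (x, w, b), backward)


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor, stride: int, padding: int) -> Tensor:
    """x (B, C_in, L) * w (C_in, C_out, K) + b -> (B, C_out, (L-1)*stride - 2*pad + K)."""
    batch, _, length = x.data.shape
    kernel = w.data.shape[2]
    c_out = w.data.shape[1]
    full = (length - 1) * stride + kernel
    t = np.einsum("bcl,cok->bolk", x.data, w.data, optimize=True)
    yp = np.zeros((batch, c_out, full))
    for k in range(kernel):
        yp[:, :, k : k + length * stride : stride] += t[:, :, :, k]
    out = yp[:, :, padding : full - padding] if padding else yp
    out = out + b.data[None, :, None]

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding)))
        gcols = _im2col(gp, kernel, stride)  # (B, C_out, L, K)
        x._accumulate(np.einsum("bolk,cok->bcl", gcols, w.data, optimize=True))
        w._accumulate(np.einsum("bcl,bolk->cok", x.data, gcols, optimize=True))
        b._accumulate(g.sum(axis=(0, 2)))

    return x._make(out, (x, w, b), backward)


def fft_magnitude(x: Tensor, n: int = 1024, eps: float = 1e-12) -> Tensor:
    """Magnitude of the n-point FFT along the last axis; differentiable.

    For real input x (zero-padded/truncated to n), with X = FFT_n(x) and
    m = |X|, the adjoint is dL/dx = Re(n * IFFT(g * X / m)) restricted to the
    original samples.
    """
    length = x.data.shape[-1]
    spectrum = np.fft.fft(x.data, n=n, axis=-1)
    mag = np.abs(spectrum)

    def backward(g):
        phase = spectrum / np.maximum(mag, eps)
        dx_full = np.real(np.fft.ifft(g * phase, axis=-1)) * n
        if length <= n:
            x._accumulate(dx_full[..., :length])
        else:  # fft truncated the input: samples past n get zero gradient
            dx = np.zeros_like(x.data)
            dx[..., :n] = dx_full
            x._accumulate(dx)

    return x._make(mag, (x,), backward)
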