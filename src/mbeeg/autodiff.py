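"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the network needs: broadcasting
arithmetic, (batched) matmul, the usual nonlinearities, stable softmax,
reductions, slicing/concat/reshape, 1-D convolution and max-pooling,
a self-adjoint FFT band mask, and dropout.  Gradients accumulate into
``Tensor.grad`` after ``backward()`` on a scalar.

The engine is intentionally small: a ``Tensor`` records its parents and
a backward closure; ``backward`` topologically sorts the graph once and
propagates.  A ``no_grad`` context disables graph construction for
inference.  Gradient correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
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
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    # -- nonlinearities ------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, alpha: float = 0.2):
        mask = self.data > 0
        slope = np.where(mask, 1.0, alpha)

        def bw(g):
            if self.requires_grad:
                self._accum(g * slope)

        return Tensor._make(self.data * slope, (self,), bw)

    def sqrt(self):
        return self**0.5

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_last(self):
        """Max over the last axis (used by max-pooling)."""
        idx = self.data.argmax(axis=-1)
        out_data = np.take_along_axis(self.data, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # -- shape ops -----------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return Tensor._make(self.data[key], (self,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    return Tensor._make(s, (x,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation), stride 1.

    ``x``: (B, C_in, T); ``w``: (C_out, C_in, K); output (B, C_out, T').
    """
    B, Cin, T = x.data.shape
    Cout, Cin_w, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv1d channel mismatch: input {Cin}, weight {Cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=-1)  # B,Cin,T',K
    out_data = np.einsum("bitk,oik->bot", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    T_out = out_data.shape[-1]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bitk,bot->oik", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k : k + T_out] += np.einsum("bot,oi->bit", g, w.data[:, :, k], optimize=True)
            x._accum(gxp[:, :, padding : padding + T] if padding else gxp)

    return Tensor._make(out_data, parents, bw)


def depthwise_conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Per-channel 1-D convolution (grouped with one filter per channel).

    ``x``: (B, C, T); ``w``: (C, K); each channel is convolved with its
    own kernel, so per-channel amplitude structure is preserved.
    """
    B, C, T = x.data.shape
    C_w, K = w.data.shape
    if C != C_w:
        raise ValueError(f"depthwise conv channel mismatch: input {C}, weight {C_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=-1)  # B,C,T',K
    out_data = np.einsum("bctk,ck->bct", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    T_out = out_data.shape[-1]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bctk,bct->ck", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k : k + T_out] += g * w.data[:, k][None, :, None]
            x._accum(gxp[:, :, padding : padding + T] if padding else gxp)

    return Tensor._make(out_data, parents, bw)


def maxpool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling over time; trailing remainder dropped."""
    B, C, T = x.data.shape
    T_out = T // size
    cropped = x[:, :, : T_out * size]
    return cropped.reshape(B, C, T_out, size).max_last()


def band_mask_fft(x: Tensor, low: float, high: float, fs: float) -> Tensor:
    """Zero all spectral content of ``x`` outside [low, high] Hz.

    Ideal (brick-wall) band selection via the real FFT along the last
    axis.  The operator is a circular convolution with a real even
    kernel, hence symmetric: the adjoint equals the operator itself, so
    the backward pass reapplies the same mask to the gradient.
    """
    T = x.data.shape[-1]
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)

    def apply(arr):
        return np.fft.irfft(np.fft.rfft(arr, axis=-1) * mask, n=T, axis=-1)

    def bw(g):
        if x.requires_grad:
            x._accum(apply(g))

    return Tensor._make(apply(x.data), (x,), bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)
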