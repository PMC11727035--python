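"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numeric engine behind every trainable layer in the package:
a :class:`Tensor` wraps an ``ndarray`` and records enough of the computation
graph to backpropagate a scalar loss.  Only the primitives the architecture
needs are implemented — elementwise math, (batched) matmul, reductions,
shape ops, stride-1/stride-2 same-padded convolution, stride-1 max pooling,
bilinear resizing, Hartley low-pass filtering and dropout.

Arrays are float64 and channels-last throughout: images ``(B, H, W, C)``,
token sequences ``(B, N, D)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.data.shape)

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            if a.requires_grad:
                a.grad += -g

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.data.shape)

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g / b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __pow__(self, k):
        assert np.isscalar(k)

        def bw(g, a=self):
            if a.requires_grad:
                a.grad += g * k * a.data ** (k - 1)

        return Tensor(self.data ** k, _parents=(self,), _backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a.grad += _unbroadcast(ga, a.data.shape)
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b.grad += _unbroadcast(gb, b.data.shape)

        return Tensor(np.matmul(self.data, other.data),
                      _parents=(self, other), _backward=bw)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            a.grad += g * o

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g, a=self):
            a.grad += g / a.data

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self, o=out_data):
            a.grad += g / (2.0 * o)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g, a=self, o=out_data):
            a.grad += g * (1.0 - o ** 2)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, a=self, o=out_data):
            a.grad += g * o * (1.0 - o)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g, a=self, m=mask):
            a.grad += g * m

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def gelu(self):
        # exact Gaussian-CDF form: x * Phi(x)
        x = self.data
        phi_cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * phi_cdf

        def bw(g, a=self, c=phi_cdf):
            x_ = a.data
            pdf = np.exp(-0.5 * x_ ** 2) / np.sqrt(2.0 * np.pi)
            a.grad += g * (c + x_ * pdf)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self):
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            a.grad += np.broadcast_to(gg, a.data.shape)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[i] for i in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bw(g, a=self):
            ref = out_data if keepdims else np.expand_dims(out_data, axis)
            gg = g if keepdims else np.expand_dims(g, axis)
            mask = (a.data == ref)
            count = mask.sum(axis=axis, keepdims=True)
            a.grad += mask * gg / count

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, a=self):
            a.grad += g.reshape(a.data.shape)

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g, a=self):
            a.grad += g.transpose(inv)

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bw)

    def __getitem__(self, idx):
        def bw(g, a=self):
            a.grad[idx] += g

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g, a=x, o=out_data):
        a.grad += o * (g - (g * o).sum(axis=axis, keepdims=True))

    return Tensor(out_data, _parents=(x,), _backward=bw)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    out_data = np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True)) + m
    soft = np.exp(x.data - out_data)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def bw(g, a=x, s=soft):
        gg = g if keepdims else np.expand_dims(g, axis)
        a.grad += gg * s

    return Tensor(out_data, _parents=(x,), _backward=bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when ``training`` is off or ``p`` is 0."""
    if not training or p <= 0.0:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.data.shape) < keep) / keep
    return x * Tensor(mask)


# -- structured primitives ---------------------------------------------

def _same_pad(n: int, k: int, s: int) -> tuple[int, int]:
    out = -(-n // s)  # ceil
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1) -> Tensor:
    """Same-padded 2-D convolution, channels last.

    ``x``: (B, H, W, Cin); ``w``: (k, k, Cin, Cout); ``b``: (Cout,).
    """
    B, H, W, Cin = x.data.shape
    k = w.data.shape[0]
    s = stride
    ph = _same_pad(H, k, s)
    pw = _same_pad(W, k, s)
    xp = np.pad(x.data, ((0, 0), ph, pw, (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B, Hp', Wp', Cin, k, k)
    win = win[:, ::s, ::s]
    Ho, Wo = win.shape[1], win.shape[2]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B, Ho, Wo, k * k * Cin)
    wmat = w.data.reshape(k * k * Cin, -1)
    out_data = cols @ wmat
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        Cout = g.shape[-1]
        if b is not None and b.requires_grad:
            b.grad += g.sum(axis=(0, 1, 2))
        if w.requires_grad:
            gw = cols.reshape(-1, k * k * Cin).T @ g.reshape(-1, Cout)
            w.grad += gw.reshape(w.data.shape)
        if x.requires_grad:
            dcols = (g @ wmat.T).reshape(B, Ho, Wo, k, k, Cin)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] += dcols[:, :, :, i, j, :]
            x.grad += dxp[:, ph[0]:ph[0] + H, pw[0]:pw[0] + W, :]

    return Tensor(out_data, _parents=parents, _backward=bw)


def max_pool2d_same(x: Tensor, window: int) -> Tensor:
    """Stride-1 same-padded sliding max over (B, H, W, C); -inf border semantics."""
    if window % 2 != 1 or window < 1:
        raise ValueError(f"max-pool window must be odd and >= 1, got {window}")
    if window == 1:
        return x
    B, H, W, C = x.data.shape
    p = window // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (window, window), axis=(1, 2))
    flat = win.reshape(B, H, W, C, window * window)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g, a=x):
        dxp = np.zeros_like(xp)
        for t in range(window * window):
            i, j = divmod(t, window)
            mask = idx == t
            dxp[:, i:i + H, j:j + W, :] += g * mask
        a.grad += dxp[:, p:p + H, p:p + W, :]

    return Tensor(out_data, _parents=(x,), _backward=bw)


_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bilinear interpolation matrix (n_out, n_in), half-pixel-center convention."""
    key = (n_in, n_out)
    if key not in _RESIZE_CACHE:
        R = np.zeros((n_out, n_in))
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        R[np.arange(n_out), lo] += 1.0 - frac
        R[np.arange(n_out), hi] += frac
        _RESIZE_CACHE[key] = R
    return _RESIZE_CACHE[key]


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of (B, H, W, C) to (B, out_h, out_w, C)."""
    B, H, W, C = x.data.shape
    Rh = _resize_matrix(H, out_h)
    Rw = _resize_matrix(W, out_w)
    # y[b,s,t,c] = sum_ij Rh[s,i] x[b,i,j,c] Rw[t,j]
    out_data = np.einsum("si,bijc,tj->bstc", Rh, x.data, Rw, optimize=True)

    def bw(g, a=x):
        a.grad += np.einsum("si,bstc,tj->bijc", Rh, g, Rw, optimize=True)

    return Tensor(out_data, _parents=(x,), _backward=bw)


def hartley_lowpass_batch(x: Tensor, rho: float) -> Tensor:
    """Hartley-domain low-pass filter on (B, H, W, C), differentiable.

    The operator is linear and self-adjoint (the DHT matrix is symmetric and
    the retained-frequency mask is diagonal), so the backward pass applies
    the same filter to the incoming gradient.
    """
    from .spectral_ops import _lowpass_apply_batch  # shared numeric kernel

    out_data = _lowpass_apply_batch(x.data, rho)

    def bw(g, a=x):
        a.grad += _lowpass_apply_batch(g, rho)

    return Tensor(out_data, _parents=(x,), _backward=bw)


# -- parameter initialisation ------------------------------------------

def glorot_uniform(rng: np.random.Generator, shape: tuple,
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Fan-in-scaled uniform init for ReLU layers."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def trunc_normal(rng: np.random.Generator, shape: tuple,
                 std: float = 0.02) -> np.ndarray:
    vals = rng.normal(0.0, std, size=shape)
    return np.clip(vals, -2.0 * std, 2.0 * std)
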