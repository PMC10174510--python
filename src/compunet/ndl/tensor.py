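"""Reverse-mode autodiff tensor.

Each ``Tensor`` wraps a float64 ndarray plus a closure computing the local
vector-Jacobian product.  ``backward()`` runs a topological sweep and
accumulates gradients into ``.grad`` of every tensor with
``requires_grad=True``.  Only what the package's networks and losses use is
implemented; shapes follow NumPy broadcasting.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` (inverse of broadcasting)."""
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
    __array_priority__ = 100  # keep numpy from hijacking ndarray op tensor

    def __init__(self, data, requires_grad: bool = False,
                 _parents=(), _backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[-1]
        self.grad = None
        self._parents = _parents if self.requires_grad or _backward else ()
        self._backward = _backward

    # -- construction ------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        t = Tensor(data, requires_grad=True)
        t._parents = parents
        t._backward = backward
        return t

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def matmul(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: (g / self.data,))

    def abs(self):
        return self._make(np.abs(self.data), (self,),
                          lambda g: (g * np.sign(self.data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,),
                          lambda g: (g * out_data * (1.0 - out_data),))

    def astype(self, dtype):
        """Cast values; gradients are cast back to the source dtype."""
        src = self.data.dtype
        return self._make(self.data.astype(dtype), (self,),
                          lambda g: (g.astype(src),))

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        return self._make(np.maximum(self.data, lo), (self,),
                          lambda g: (g * mask,))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def _extreme(self, axis, keepdims, fn):
        out_data = fn(self.data, axis=axis, keepdims=True)
        mask = self.data == out_data  # ties share gradient equally
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            return (mask * (gg / counts),)

        res = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._make(res, (self,), backward)

    def max(self, axis: int, keepdims: bool = False):
        return self._extreme(axis, keepdims, np.max)

    def min(self, axis: int, keepdims: bool = False):
        return self._extreme(axis, keepdims, np.min)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._make(self.data.transpose(*axes), (self,),
                          lambda g: (g.transpose(*inv),))

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    def pad2d(self, pad: tuple[int, int, int, int]):
        """Zero-pad the trailing two axes by (top, bottom, left, right)."""
        t, b, l, r = pad
        width = [(0, 0)] * (self.ndim - 2) + [(t, b), (l, r)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(t, out_data.shape[-2] - b),
              slice(l, out_data.shape[-1] - r))
        return self._make(out_data, (self,), lambda g: (g[sl],))

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of the trailing two axes."""
        out_data = self.data.repeat(2, axis=-2).repeat(2, axis=-1)

        def backward(g):
            n, h2, w2 = g.shape[:-2], g.shape[-2], g.shape[-1]
            gg = g.reshape(*n, h2 // 2, 2, w2 // 2, 2)
            return (gg.sum(axis=(-3, -1)),)

        return self._make(out_data, (self,), backward)

    # -- convolution -------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2D cross-correlation: x (N,C,H,W) * w (O,C,kh,kw) -> (N,O,Ho,Wo)."""
        x, w = self, self._wrap(weight)
        N, C, H, W = x.shape
        O, C2, kh, kw = w.shape
        if C != C2:
            raise ValueError(f"conv2d channel mismatch: {C} vs {C2}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                             (padding, padding))) if padding else x.data
        Hp, Wp = xp.shape[2], xp.shape[3]
        Ho = (Hp - kh) // stride + 1
        Wo = (Wp - kw) // stride + 1
        # one GEMM over all kernel taps, then shifted-slice accumulation:
        # avoids materialising the (N,C,Ho,Wo,kh,kw) im2col tensor
        xs = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))      # (N,Hp,Wp,C)
        wt = np.ascontiguousarray(w.data.transpose(1, 2, 3, 0)).reshape(C, kh * kw * O)
        y = (xs.reshape(-1, C) @ wt).reshape(N, Hp, Wp, kh, kw, O)
        acc = np.zeros((N, Ho, Wo, O), dtype=y.dtype)
        for i in range(kh):
            for j in range(kw):
                acc += y[:, i:i + stride * Ho:stride,
                         j:j + stride * Wo:stride, i, j, :]
        out_data = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
        if bias is not None:
            out_data += bias.data.reshape(1, O, 1, 1)

        def backward(g):
            gT = np.ascontiguousarray(g.transpose(0, 2, 3, 1))   # (N,Ho,Wo,O)
            wo = np.ascontiguousarray(w.data.transpose(0, 2, 3, 1)).reshape(O, kh * kw * C)
            gy = (gT.reshape(-1, O) @ wo).reshape(N, Ho, Wo, kh, kw, C)
            gxs = np.zeros_like(xs)
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    sl = (slice(None), slice(i, i + stride * Ho, stride),
                          slice(j, j + stride * Wo, stride), slice(None))
                    gxs[sl] += gy[:, :, :, i, j, :]
                    gw[:, :, i, j] = np.tensordot(gT, xs[sl],
                                                  axes=([0, 1, 2], [0, 1, 2]))
            gxp = gxs.transpose(0, 3, 1, 2)
            gx = gxp[:, :, padding:padding + H, padding:padding + W] \
                if padding else gxp
            grads = [np.ascontiguousarray(gx), gw]
            if bias is not None:
                grads.append(g.sum(axis=(0, 2, 3)))
            return tuple(grads)

        parents = (x, w) if bias is None else (x, w, bias)
        return self._make(out_data, parents, backward)

    # -- autodiff ----------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
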