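"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists so that every model in this package — convolutional
streams, recurrent cells, attention blocks — exposes its full computation
graph to the training loop and, for the traced families, to layer-wise
relevance propagation. Only the operations the models need are implemented;
each primitive stores a closure that accumulates gradients into its parents.

Tensors are thin wrappers around ``numpy.ndarray``. Gradient flow is opt-in
via ``requires_grad``; constants (data batches, masks) stay plain arrays or
non-grad tensors and cost nothing at backward time.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "softmax_cross_entropy", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    # --------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = grad
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @staticmethod
    def _accumulate(t: "Tensor", g: np.ndarray):
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = g.copy()
        else:
            t.grad = t.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, out_req, (self, other))

        def bwd(g):
            Tensor._accumulate(self, _unbroadcast(g, self.shape))
            Tensor._accumulate(other, _unbroadcast(g, other.shape))

        out._backward = bwd if out_req else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, -g)

        out._backward = bwd if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, out_req, (self, other))

        def bwd(g):
            Tensor._accumulate(self, _unbroadcast(g * other.data, self.shape))
            Tensor._accumulate(other, _unbroadcast(g * self.data, other.shape))

        out._backward = bwd if out_req else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data / other.data, out_req, (self, other))

        def bwd(g):
            Tensor._accumulate(self, _unbroadcast(g / other.data, self.shape))
            Tensor._accumulate(
                other, _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        out._backward = bwd if out_req else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, g * p * self.data ** (p - 1))

        out._backward = bwd if self.requires_grad else None
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, out_req, (self, other))

        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            Tensor._accumulate(self, _unbroadcast(ga, self.shape))
            Tensor._accumulate(other, _unbroadcast(gb, other.shape))

        out._backward = bwd if out_req else None
        return out

    # ------------------------------------------------------------------ unary
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, g * val)

        out._backward = bwd if self.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, g / self.data)

        out._backward = bwd if self.requires_grad else None
        return out

    def sqrt(self):
        return self**0.5

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, g * (1.0 - val**2))

        out._backward = bwd if self.requires_grad else None
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, g * val * (1.0 - val))

        out._backward = bwd if self.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, g * mask)

        out._backward = bwd if self.requires_grad else None
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if axis is None:
                gg = np.broadcast_to(g, self.shape)
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    for ax in sorted(a % self.ndim for a in axes):
                        g = np.expand_dims(g, ax)
                gg = np.broadcast_to(g, self.shape)
            Tensor._accumulate(self, gg.astype(self.dtype, copy=False))

        out._backward = bwd if self.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim]
             for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims=False):
        val = self.data.max(axis=axis, keepdims=True)
        out_val = val if keepdims or axis is None else np.squeeze(val, axis=axis)
        if axis is None and not keepdims:
            out_val = self.data.max()
        out = Tensor(out_val, self.requires_grad, (self,))

        def bwd(g):
            mask = (self.data == val).astype(self.dtype)
            mask /= mask.sum(axis=axis, keepdims=True)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accumulate(self, mask * g)

        out._backward = bwd if self.requires_grad else None
        return out

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, g.reshape(self.shape))

        out._backward = bwd if self.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bwd(g):
            Tensor._accumulate(self, g.transpose(inv))

        out._backward = bwd if self.requires_grad else None
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            Tensor._accumulate(self, full)

        out._backward = bwd if self.requires_grad else None
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 out_req, tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]

    def bwd(g):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            Tensor._accumulate(t, piece)

    out._backward = bwd if out_req else None
    return out


def conv1d(x, w, b=None, stride: int = 1, dilation: int = 1,
           padding=(0, 0)) -> Tensor:
    """Temporal convolution.

    x: (N, T, C_in); w: (K, C_in, C_out); b: (C_out,) or None.
    ``padding`` is an explicit (left, right) zero-pad; the caller computes
    'same' or 'causal' pads. Implemented as K strided slice-matmuls, which is
    both memory-light and fast for the small kernels used here.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    pl, pr = padding
    xd = x.data
    if pl or pr:
        xd = np.pad(xd, ((0, 0), (pl, pr), (0, 0)))
    N, Tp, Cin = xd.shape
    K = w.shape[0]
    span = (K - 1) * dilation + 1
    if span > Tp:
        raise ValueError(
            f"kernel span {span} exceeds padded length {Tp}"
        )
    T_out = (Tp - span) // stride + 1
    out_val = np.zeros((N, T_out, w.shape[2]), dtype=xd.dtype)
    for k in range(K):
        sl = xd[:, k * dilation: k * dilation + stride * T_out: stride, :]
        out_val += sl @ w.data[k]
    if b is not None:
        out_val = out_val + b.data
    parents = (x, w) + ((b,) if b is not None else ())
    out_req = any(t.requires_grad for t in parents)
    out = Tensor(out_val, out_req, parents)

    def bwd(g):
        if x.requires_grad:
            gxp = np.zeros_like(xd)
            for k in range(K):
                gxp[:, k * dilation: k * dilation + stride * T_out: stride,
                    :] += g @ w.data[k].T
            gx = gxp[:, pl: Tp - pr if pr else None, :]
            Tensor._accumulate(x, gx)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for k in range(K):
                sl = xd[:, k * dilation: k * dilation + stride * T_out: stride, :]
                gw[k] = np.tensordot(sl, g, axes=([0, 1], [0, 1]))
            Tensor._accumulate(w, gw)
        if b is not None and b.requires_grad:
            Tensor._accumulate(b, g.sum(axis=(0, 1)))

    out._backward = bwd if out_req else None
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy computed stably from logits."""
    shift = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    lse = shift.exp().sum(axis=-1, keepdims=True).log()
    logp = shift - lse
    n = logits.shape[0]
    return -(as_tensor(onehot) * logp).sum() / float(n)
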