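"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

The coefficient network and every loss in this package are tiny by deep
learning standards (a four-layer MLP with ~6e3 parameters), so a small
tape-based engine over float64 numpy arrays is sufficient and keeps the
package free of heavyweight framework dependencies.  The op set is exactly
what the losses need: broadcasting arithmetic, matmul, the usual smooth
scalars (exp/log/sqrt/sigmoid/softplus/swish), reductions, gather/sort and
stacking.  Gradients flow through sorting via the (piecewise-constant)
argsort permutation, which is the standard quantile-coupling treatment of
the 1-D Wasserstein distance.

Usage mirrors the micrograd pattern::

    x = Tensor(np.ones(3), requires_grad=True)
    y = (x * 2.0 + 1.0).sum()
    y.backward()
    x.grad  # -> array of 2.0
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import expit as _expit

__all__ = ["Tensor", "as_tensor", "stack", "concatenate", "no_value",
           "default_dtype", "use_dtype"]

_DTYPE = [np.float64]


def default_dtype():
    """The dtype new tensors are created with (float64 outside training)."""
    return _DTYPE[0]


@contextmanager
def use_dtype(dt):
    """Temporarily switch the tensor dtype (e.g. float32 during training)."""
    old = _DTYPE[0]
    _DTYPE[0] = np.dtype(dt).type
    try:
        yield
    finally:
        _DTYPE[0] = old


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes broadcast from 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape machinery to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer binary ops to the reflected Tensor dunders
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE[0])
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in _parents)
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None
        self.grad = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=self.data.dtype)
        if g.shape != self.data.shape:
            g = np.broadcast_to(g, self.data.shape)
        # grads are only ever replaced (never mutated in place), so views are safe
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS; the Euler-Maruyama unroll can be thousands of nodes deep
        visiting: list[tuple[Tensor, int]] = [(self, 0)]
        stack_.clear()
        while visiting:
            node, state = visiting.pop()
            if state == 0:
                if id(node) in seen:
                    continue
                seen.add(id(node))
                visiting.append((node, 1))
                for p in node._parents:
                    if p.requires_grad and id(p) not in seen:
                        visiting.append((p, 0))
            else:
                topo.append(node)
        self.grad = (
            np.ones_like(self.data)
            if grad is None
            else np.asarray(grad, dtype=self.data.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g, b.data.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g * a.data, b.data.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accumulate(
                        _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)
                    )
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** p, _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, p=p):
                a._accumulate(g * p * a.data ** (p - 1))
            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad:
                    b._accumulate(a.data.T @ g)
            out._backward = _bw
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self):
                a._accumulate(g.reshape(a.data.shape))
            out._backward = _bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, key=key):
                gi = np.zeros_like(a.data)
                np.add.at(gi, key, g)
                a._accumulate(gi)
            out._backward = _bw
        return out

    def take_along_axis(self, indices: np.ndarray, axis: int):
        indices = np.asarray(indices)
        axis = axis if axis >= 0 else self.ndim + axis
        out = Tensor(np.take_along_axis(self.data, indices, axis=axis),
                     _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, idx=indices, axis=axis):
                gi = np.zeros_like(a.data)
                # build fancy index tuple addressing each gathered element
                grids = list(
                    np.meshgrid(*[np.arange(s) for s in idx.shape], indexing="ij")
                )
                grids[axis] = idx
                np.add.at(gi, tuple(grids), g)
                a._accumulate(gi)
            out._backward = _bw
        return out

    def sort(self, axis: int = -1):
        """Sort along `axis`; gradients follow the sorting permutation."""
        idx = np.argsort(self.data, axis=axis, kind="stable")
        return self.take_along_axis(idx, axis=axis if axis >= 0 else self.ndim - 1)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None):
        out = Tensor(self.data.max(axis=axis), _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, axis=axis):
                if axis is None:
                    mask = (a.data == a.data.max()).astype(np.float64)
                    mask /= mask.sum()
                    a._accumulate(mask * g)
                else:
                    mx = np.expand_dims(a.data.max(axis=axis), axis)
                    mask = (a.data == mx).astype(np.float64)
                    mask /= mask.sum(axis=axis, keepdims=True)
                    a._accumulate(mask * np.expand_dims(g, axis))
            out._backward = _bw
        return out

    def var(self, axis=None, ddof: int = 1):
        """Sample variance (unbiased by default), differentiable."""
        mu = self.mean(axis=axis, keepdims=axis is not None)
        centered = self - mu
        n = self.data.size if axis is None else self.data.shape[axis]
        return (centered * centered).sum(axis=axis) * (1.0 / (n - ddof))

    # ------------------------------------------------------- elementwise math
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, e=e):
                a._accumulate(g * e)
            out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self):
                a._accumulate(g / a.data)
            out._backward = _bw
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, r=r):
                a._accumulate(g * 0.5 / r)
            out._backward = _bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self):
                a._accumulate(g * np.sign(a.data))
            out._backward = _bw
        return out

    def sin(self):
        out = Tensor(np.sin(self.data), _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self):
                a._accumulate(g * np.cos(a.data))
            out._backward = _bw
        return out

    def sigmoid(self):
        s = _expit(self.data)
        out = Tensor(s, _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, s=s):
                a._accumulate(g * s * (1.0 - s))
            out._backward = _bw
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data), _parents=(self,))
        if out.requires_grad:
            s = _expit(self.data)
            def _bw(g, a=self, s=s):
                a._accumulate(g * s)
            out._backward = _bw
        return out

    def swish(self):
        """x * sigmoid(x), fused into one tape node (backward is closed form)."""
        s = _expit(self.data)
        out = Tensor(self.data * s, _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, s=s):
                a._accumulate(g * (s * (1.0 + a.data * (1.0 - s))))
            out._backward = _bw
        return out

    def swish_prime(self):
        """d/dz of swish, s(1 + z(1-s)); backward uses the closed-form
        second derivative s(1-s)(2 + z(1-2s)), so this node can sit inside a
        loss that is itself differentiated (forward-over-reverse pattern)."""
        s = _expit(self.data)
        out = Tensor(s * (1.0 + self.data * (1.0 - s)), _parents=(self,))
        if out.requires_grad:
            def _bw(g, a=self, s=s):
                a._accumulate(g * (s * (1.0 - s) * (2.0 + a.data * (1.0 - 2.0 * s))))
            out._backward = _bw
        return out

    def maximum(self, other):
        """Elementwise max; at ties the gradient is split evenly."""
        other = as_tensor(other)
        out = Tensor(np.maximum(self.data, other.data), _parents=(self, other))
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                ga = np.where(a.data > b.data, 1.0,
                              np.where(a.data == b.data, 0.5, 0.0))
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g * ga, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g * (1.0 - ga), b.data.shape))
            out._backward = _bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack(tensors, axis: int = 0) -> Tensor:
    """Stack tensors (or arrays) along a new axis, tracking gradients."""
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    if out.requires_grad:
        def _bw(g, ts=tensors, axis=axis):
            pieces = np.moveaxis(g, axis, 0)
            for t, piece in zip(ts, pieces):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = _bw
    return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors)
    )
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def _bw(g, ts=tensors, axis=axis, offsets=offsets):
            for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])
        out._backward = _bw
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused affine map x @ w + b as a single tape node."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    out = Tensor(x.data @ w.data + b.data, _parents=(x, w, b))
    if out.requires_grad:
        def _bw(g, x=x, w=w, b=b):
            if x.requires_grad:
                x._accumulate(g @ w.data.T)
            if w.requires_grad:
                w._accumulate(x.data.T @ g)
            if b.requires_grad:
                b._accumulate(g.sum(axis=0))
        out._backward = _bw
    return out


def no_value(x):
    """Return the plain ndarray behind `x` (Tensor or array-like)."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)
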