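"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core behind the TabNet encoders, projection heads and
neural baselines in this package.  It implements exactly the operator set
those models need — broadcasting arithmetic, matmul, GLU-style
nonlinearities, reductions, column slicing/concatenation and sparsemax —
with a topologically-ordered backward pass and an Adam optimizer.

All computation is float64 NumPy on CPU, which keeps runs bit-reproducible
for a fixed seed.  Gradient correctness is validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "sparsemax_np"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def sparsemax_np(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of ``v`` onto the probability simplex.

    Sorted-threshold algorithm: sort each row in decreasing order, find the
    largest support size k with 1 + k*z_(k) > cumsum(z)_(k), set the
    threshold tau = (cumsum(z)_(k) - 1)/k and clip.  Produces exact zeros.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("sparsemax of an empty vector is undefined")
    if not np.all(np.isfinite(v)):
        raise ValueError("sparsemax input must be finite")
    one_d = v.ndim == 1
    z = np.atleast_2d(v)
    zs = np.sort(z, axis=-1)[:, ::-1]
    cz = np.cumsum(zs, axis=-1)
    k = np.arange(1, z.shape[-1] + 1)
    support = 1.0 + k * zs > cz
    k_star = support.sum(axis=-1)
    tau = (np.take_along_axis(cz, k_star[:, None] - 1, axis=-1) - 1.0) / k_star[:, None]
    out = np.maximum(z - tau, 0.0)
    return out[0] if one_d else out


class Tensor:
    """A NumPy array with an autograd tape.

    Only nodes created with ``requires_grad=True`` (parameters) or derived
    from such nodes accumulate gradients.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._node(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g, a=self, p=exponent):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._node(self.data ** exponent, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._node(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._node(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return self._node(s, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward(g, a=self, e=e):
            if a.requires_grad:
                a._accum(g * e)

        return self._node(e, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._node(np.log(self.data), (self,), backward)

    def sparsemax(self) -> "Tensor":
        """Row-wise simplex projection.  Jacobian-vector product uses the
        support set: dL/dv_i = 1[p_i>0] * (g_i - mean of g over the support)."""
        p = sparsemax_np(self.data)

        def backward(g, a=self, p=p):
            if not a.requires_grad:
                return
            supp = p > 0
            g2 = np.atleast_2d(g)
            s2 = np.atleast_2d(supp)
            vhat = (g2 * s2).sum(axis=-1, keepdims=True) / s2.sum(axis=-1, keepdims=True)
            grad = np.where(s2, g2 - vhat, 0.0)
            a._accum(grad.reshape(a.data.shape))

        return self._node(p, (self,), backward)

    # -- reductions & reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cols(self, start: int, stop: int) -> "Tensor":
        """Slice of the last axis (used to split GLU / decision-attention halves)."""

        def backward(g, a=self, start=start, stop=stop):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[..., start:stop] = g
                a._accum(full)

        return self._node(self.data[..., start:stop], (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]

        def backward(g, ts=tensors, sizes=sizes, axis=axis):
            offset = 0
            for t, s in zip(ts, sizes):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(offset, offset + s)
                    t._accum(g[tuple(idx)])
                offset += s

        return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)

    # -- composite helpers ----------------------------------------------------
    def l2_normalize_rows(self, eps: float = 1e-12) -> "Tensor":
        norm = ((self * self).sum(axis=-1, keepdims=True) + eps) ** 0.5
        return self / norm

    def logsumexp_rows(self) -> "Tensor":
        """Row-wise log-sum-exp, max-shifted for stability (the shift is a
        constant and does not affect the gradient)."""
        m = self.data.max(axis=-1, keepdims=True)
        return (self - Tensor(m)).exp().sum(axis=-1, keepdims=True).log() + Tensor(m)

    # -- backprop -------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._backward is not None:
                node._backward(node.grad)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
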