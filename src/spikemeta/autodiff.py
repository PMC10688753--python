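"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports the operations needed to train the variational deep-GP and the
masked autoregressive flow: broadcasting arithmetic, matmul (including
stacked/batched), elementwise transcendentals, reductions, reshapes,
Cholesky factorization and triangular solves.  Gradients of the linear-algebra
primitives follow the standard matrix-calculus results and are verified
against finite differences in the test suite.

Not a general framework: no views, no in-place ops, graphs are rebuilt every
step (define-by-run).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

__all__ = ["Tensor", "Parameter", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph machinery --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def backward(self):
        order = []
        seen = set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += -g
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1.0)
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += _unbroadcast(ga, self.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += _unbroadcast(gb, other.shape)
        out._backward = bwd
        return out

    # -- elementwise -------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * val
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g / self.data
        out._backward = bwd
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * 0.5 / val
        out._backward = bwd
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * (1.0 - val * val)
        out._backward = bwd
        return out

    def softplus(self):
        # numerically stable log(1 + exp(x))
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g / (1.0 + np.exp(-self.data))
        out._backward = bwd
        return out

    def clip_min(self, floor: float):
        """max(x, floor); gradient passes only where x > floor."""
        mask = self.data > floor
        out = Tensor(np.where(mask, self.data, floor), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * mask
        out._backward = bwd
        return out

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.shape)
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(self.shape)
        out._backward = bwd
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(np.transpose(self.data, axes), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            inv = None if axes is None else np.argsort(axes)
            self.grad += np.transpose(g, inv)
        out._backward = bwd
        return out

    @property
    def T(self):
        return self.transpose()

    def swap_last(self):
        """Transpose the last two axes (batched matrix transpose)."""
        nd = self.ndim
        axes = tuple(range(nd - 2)) + (nd - 1, nd - 2)
        return self.transpose(*axes)

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                np.add.at(self.grad, key, g)
        out._backward = bwd
        return out

    # -- linear algebra ----------------------------------------------------
    def cholesky(self):
        """Lower Cholesky factor of a symmetric positive-definite matrix."""
        L = np.linalg.cholesky(self.data)
        out = Tensor(L, parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            # A_bar = 0.5 * L^{-T} (P + P^T) L^{-1}, P = Phi(L^T Lbar)
            P = np.tril(L.T @ g)
            P[np.diag_indices_from(P)] *= 0.5
            S = 0.5 * (P + P.T)
            tmp = solve_triangular(L, S, lower=True, trans="T")
            abar = solve_triangular(L, tmp.T, lower=True, trans="T").T
            self.grad += 0.5 * (abar + abar.T)
        out._backward = bwd
        return out

    def tri_solve(self, b: "Tensor", trans: bool = False):
        """Solve L Y = B (or L^T Y = B when trans) for lower-triangular self."""
        b = self._lift(b)
        L = self.data
        Y = solve_triangular(L, b.data, lower=True,
                             trans="T" if trans else "N")
        out = Tensor(Y, parents=(self, b))

        def bwd(g):
            gb = solve_triangular(L, g, lower=True,
                                  trans="N" if trans else "T")
            if b.requires_grad:
                b.grad += gb
            if self.requires_grad:
                if trans:
                    gL = -Y @ gb.T if Y.ndim > 1 else -np.outer(Y, gb)
                else:
                    gL = -gb @ Y.T if Y.ndim > 1 else -np.outer(gb, Y)
                self.grad += np.tril(gL)
        out._backward = bwd
        return out


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.grad += g[tuple(idx)]
    out._backward = bwd
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.array(data, dtype=float), requires_grad=True)


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
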