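"""Vectorized forward-mode automatic differentiation on small closed op set.

A :class:`Jet` carries values with shape ``(...,)`` and tangents with shape
``(..., n_dir)`` for a fixed number of seed directions.  All continuous-time
physics in this package is written against the ops defined here, so exact
first derivatives of every dynamics residual are available at every
collocation point without symbolic processing.  Smoothness is a modeling
requirement (interior-point style solvers need C1 residuals), so the op set
deliberately excludes branches, abs and hard clamps; smooth replacements
(softplus, sigmoid, tanh) are primitives.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Jet", "seed", "value", "grad", "asjet",
    "sin", "cos", "exp", "log", "sqrt", "tanh", "sigmoid", "softplus",
]


class Jet:
    __slots__ = ("v", "g")
    # keep numpy from absorbing Jets into object arrays: binary ops between
    # an ndarray and a Jet must dispatch to the reflected Jet operator
    __array_ufunc__ = None

    def __init__(self, v, g):
        self.v = np.asarray(v, dtype=float)
        self.g = np.asarray(g, dtype=float)

    # ---- arithmetic -------------------------------------------------
    def __add__(self, o):
        if isinstance(o, Jet):
            return Jet(self.v + o.v, self.g + o.g)
        return Jet(self.v + o, _bg(self.g, np.shape(self.v + o)))

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.v, -self.g)

    def __sub__(self, o):
        return self + (-o if isinstance(o, Jet) else -np.asarray(o))

    def __rsub__(self, o):
        return (-self) + o

    def __mul__(self, o):
        if isinstance(o, Jet):
            return Jet(self.v * o.v,
                       self.g * o.v[..., None] + o.g * self.v[..., None])
        o = np.asarray(o, dtype=float)
        return Jet(self.v * o, self.g * o[..., None])

    __rmul__ = __mul__

    def __truediv__(self, o):
        if isinstance(o, Jet):
            inv = 1.0 / o.v
            v = self.v * inv
            return Jet(v, (self.g - o.g * v[..., None]) * inv[..., None])
        o = np.asarray(o, dtype=float)
        return Jet(self.v / o, self.g / o[..., None])

    def __rtruediv__(self, o):
        o = np.asarray(o, dtype=float)
        inv = 1.0 / self.v
        v = o * inv
        return Jet(v, -self.g * (v * inv)[..., None])

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("Jet ** exponent must be a scalar")
        v = self.v ** p
        return Jet(v, (p * self.v ** (p - 1))[..., None] * self.g)

    def __repr__(self):  # pragma: no cover
        return f"Jet(v={self.v!r})"


def _bg(g, vshape):
    """Broadcast a tangent block to match a broadcasted value shape."""
    if g.shape[:-1] == tuple(vshape):
        return g
    return np.broadcast_to(g, tuple(vshape) + (g.shape[-1],))


def seed(*values):
    """Create Jets for ``values`` with identity tangent directions.

    Each argument is a value array; direction ``i`` is a unit perturbation of
    argument ``i``.  Returns a list of Jets sharing the same direction basis.
    """
    values = [np.asarray(v, dtype=float) for v in values]
    n = len(values)
    out = []
    for i, v in enumerate(values):
        g = np.zeros(v.shape + (n,))
        g[..., i] = 1.0
        out.append(Jet(v, g))
    return out


def asjet(x, like):
    """Lift a constant to a Jet with zero tangents in the basis of ``like``."""
    if isinstance(x, Jet):
        return x
    x = np.asarray(x, dtype=float)
    return Jet(x, np.zeros(x.shape + (like.g.shape[-1],)))


def value(x):
    return x.v if isinstance(x, Jet) else np.asarray(x, dtype=float)


def grad(x):
    return x.g if isinstance(x, Jet) else None


def _unary(x, f, df):
    if isinstance(x, Jet):
        return Jet(f(x.v), df(x.v)[..., None] * x.g)
    return f(np.asarray(x, dtype=float))


def sin(x):
    return _unary(x, np.sin, np.cos)


def cos(x):
    return _unary(x, np.cos, lambda v: -np.sin(v))


def exp(x):
    return _unary(x, np.exp, np.exp)


def log(x):
    return _unary(x, np.log, lambda v: 1.0 / v)


def sqrt(x):
    return _unary(x, np.sqrt, lambda v: 0.5 / np.sqrt(v))


def tanh(x):
    return _unary(x, np.tanh, lambda v: 1.0 - np.tanh(v) ** 2)


def _sigmoid(v):
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def sigmoid(x):
    return _unary(x, _sigmoid, lambda v: _sigmoid(v) * (1.0 - _sigmoid(v)))


def _softplus(v):
    # log(1 + e^v), overflow-safe
    return np.logaddexp(0.0, v)


def softplus(x):
    """Smooth max(0, x); derivative is the logistic sigmoid."""
    return _unary(x, _softplus, _sigmoid)
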