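"""Minimal forward-mode differentiation on numpy arrays.

A :class:`Jet` carries a value array together with its Jacobian with respect
to a flat vector of independent variables (last axis = variable index).  It
supports exactly the operations needed by the ovoid steric term: arithmetic,
powers, square roots, dot/cross products and normalization.  Derivatives are
exact for the implemented expressions, so gradient checks against central
finite differences are limited only by the finite-difference error itself.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Jet", "seed_jets"]


class Jet:
    """Value + partial derivatives w.r.t. a fixed set of variables.

    Parameters
    ----------
    val : ndarray, shape ``S``
        The value.
    jac : ndarray, shape ``S + (nvars,)``
        Partial derivatives of each entry of ``val``.
    """

    __slots__ = ("val", "jac")
    __array_priority__ = 100  # so ndarray * Jet dispatches here

    def __init__(self, val, jac):
        self.val = np.asarray(val, dtype=float)
        self.jac = np.asarray(jac, dtype=float)

    # -- helpers ---------------------------------------------------------
    @property
    def nvars(self) -> int:
        return self.jac.shape[-1]

    @staticmethod
    def constant(val, nvars):
        val = np.asarray(val, dtype=float)
        return Jet(val, np.zeros(val.shape + (nvars,)))

    def _coerce(self, other):
        if isinstance(other, Jet):
            return other
        return Jet.constant(other, self.nvars)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = self._coerce(other)
        return Jet(self.val + o.val, self.jac + o.jac)

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.val, -self.jac)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Jet(
            self.val * o.val,
            self.jac * o.val[..., None] + o.jac * self.val[..., None],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        inv = 1.0 / o.val
        val = self.val * inv
        jac = (self.jac - o.jac * val[..., None]) * inv[..., None]
        return Jet(val, jac)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        val = self.val ** exponent
        jac = exponent * self.val ** (exponent - 1.0)
        return Jet(val, self.jac * jac[..., None])

    # -- elementary functions -------------------------------------------
    def sqrt(self):
        s = np.sqrt(self.val)
        return Jet(s, self.jac * (0.5 / s)[..., None])

    # -- reductions over the leading (vector) axis -----------------------
    def sum(self):
        return Jet(self.val.sum(axis=0), self.jac.sum(axis=0))

    def dot(self, other):
        """Inner product over the first axis (3-vectors)."""
        o = self._coerce(other)
        val = np.sum(self.val * o.val, axis=0)
        jac = np.sum(
            self.jac * o.val[..., None] + o.jac * self.val[..., None], axis=0
        )
        return Jet(val, jac)

    def norm(self):
        return self.dot(self).sqrt()

    def cross(self, other):
        """Cross product of two 3-vector jets (first axis length 3)."""
        o = self._coerce(other)
        a, b = self, o

        def comp(i, j, k):
            return a[j] * b[k] - a[k] * b[j]

        return Jet.stack([comp(0, 1, 2), comp(1, 2, 0), comp(2, 0, 1)])

    def __getitem__(self, idx):
        return Jet(self.val[idx], self.jac[idx])

    @staticmethod
    def stack(jets):
        return Jet(
            np.stack([j.val for j in jets]), np.stack([j.jac for j in jets])
        )


def seed_jets(values: np.ndarray) -> Jet:
    """Promote a flat variable vector to a Jet with identity Jacobian."""
    values = np.asarray(values, dtype=float).ravel()
    return Jet(values, np.eye(values.size))
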