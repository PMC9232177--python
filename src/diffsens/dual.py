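"""Minimal dual-number carrier for forward-mode differentiation.

A dual number ``a + b·ε`` (with ``ε² = 0``) propagates a value together
with a vector of first-order partials through elementary arithmetic.
Seeding several unit directions at once ("chunking") yields several
Jacobian columns per function evaluation.  Only first-order partials are
carried; second derivatives are the province of the complex-step engine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dual", "DualOperationError"]


class DualOperationError(TypeError):
    """A primitive not supported by the dual-number carrier was invoked."""

    def __init__(self, op: str):
        super().__init__(
            f"operation {op!r} is not supported on dual numbers; supported "
            "primitives are +, -, *, /, **, exp, log, sin, cos, sqrt"
        )


class Dual:
    """Value plus a vector of partial derivatives.

    Parameters
    ----------
    val : float
        Primal value.
    der : ndarray
        Partials of the value with respect to the seeded directions.
    """

    __slots__ = ("val", "der")
    # keep numpy from broadcasting over us elementwise in mixed expressions
    __array_priority__ = 100.0

    def __init__(self, val, der):
        self.val = float(val)
        self.der = np.asarray(der, dtype=float)

    # -- helpers -----------------------------------------------------------
    @classmethod
    def _lift(cls, other, width):
        if isinstance(other, Dual):
            return other
        if isinstance(other, (int, float, np.integer, np.floating)):
            return cls(other, np.zeros(width))
        return None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = Dual._lift(other, self.der.size)
        if o is None:
            return NotImplemented
        return Dual(self.val + o.val, self.der + o.der)

    __radd__ = __add__

    def __neg__(self):
        return Dual(-self.val, -self.der)

    def __sub__(self, other):
        o = Dual._lift(other, self.der.size)
        if o is None:
            return NotImplemented
        return Dual(self.val - o.val, self.der - o.der)

    def __rsub__(self, other):
        o = Dual._lift(other, self.der.size)
        if o is None:
            return NotImplemented
        return Dual(o.val - self.val, o.der - self.der)

    def __mul__(self, other):
        o = Dual._lift(other, self.der.size)
        if o is None:
            return NotImplemented
        return Dual(self.val * o.val, self.der * o.val + self.val * o.der)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Dual._lift(other, self.der.size)
        if o is None:
            return NotImplemented
        return Dual(
            self.val / o.val,
            (self.der * o.val - self.val * o.der) / o.val**2,
        )

    def __rtruediv__(self, other):
        o = Dual._lift(other, self.der.size)
        if o is None:
            return NotImplemented
        return o.__truediv__(self)

    def __pow__(self, other):
        if isinstance(other, (int, float, np.integer, np.floating)):
            return Dual(
                self.val**other,
                other * self.val ** (other - 1) * self.der,
            )
        o = Dual._lift(other, self.der.size)
        if o is None:
            return NotImplemented
        # x**y = exp(y log x)
        return (o * self.log()).exp()

    def __rpow__(self, other):
        o = Dual._lift(other, self.der.size)
        if o is None:
            return NotImplemented
        return o.__pow__(self)

    # -- analytic primitives (numpy dispatches to these on object input) --
    def exp(self):
        e = np.exp(self.val)
        return Dual(e, e * self.der)

    def log(self):
        return Dual(np.log(self.val), self.der / self.val)

    def sin(self):
        return Dual(np.sin(self.val), np.cos(self.val) * self.der)

    def cos(self):
        return Dual(np.cos(self.val), -np.sin(self.val) * self.der)

    def sqrt(self):
        r = np.sqrt(self.val)
        return Dual(r, self.der / (2.0 * r))

    # -- explicitly unsupported primitives --------------------------------
    def __abs__(self):
        raise DualOperationError("abs")

    def __floordiv__(self, other):
        raise DualOperationError("floordiv")

    def __mod__(self, other):
        raise DualOperationError("mod")

    def tan(self):
        raise DualOperationError("tan")

    def __repr__(self):  # pragma: no cover
        return f"Dual({self.val!r}, {self.der!r})"
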