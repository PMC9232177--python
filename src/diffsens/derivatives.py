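"""Generic derivative engines for vector-valued functions of parameters.

Four first-order engines are provided — complex step, forward differences,
central differences, and a dual-number forward mode — together with a
complex-step Hessian that handles mixed partials via rotated perturbations
``e^{iπ/4}Δ`` along coordinate-pair directions.

The complex-step approximation ``f'(p) ≈ Imag f(p + iΔ)/Δ`` is exact to
``O(Δ²)`` for analytic ``f`` and involves no subtractive cancellation, so
Δ can be taken near machine precision (default ``1e-12``).  The Hessian
variant carries ``O(Δ⁴)`` truncation error but reintroduces roundoff, so
its default step is ``1e-4``.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dual import Dual

__all__ = [
    "TargetFunction",
    "DerivativeResult",
    "HessianResult",
    "complex_step_jacobian",
    "complex_step_hessian",
    "forward_difference_jacobian",
    "central_difference_jacobian",
    "dual_jacobian",
    "directional_derivative",
]

#: default perturbation for first-order complex step
DEFAULT_STEP_FIRST = 1e-12
#: default perturbation for the second-order (Hessian) complex step
DEFAULT_STEP_SECOND = 1e-4

_ROT45 = (1.0 + 1.0j) / np.sqrt(2.0)


@dataclass(frozen=True)
class TargetFunction:
    """A differentiable map from a parameter vector to an output vector.

    ``evaluate`` must accept real vectors and, for the complex-step
    engines, vectors with infinitesimal imaginary parts.  ``analytic``
    asserts the implementation uses only analytic elementary operations
    (no absolute values, branches on parameter values, max/min,
    rounding); the complex-step engines warn when it is False.
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    n_params: int
    n_outputs: int
    analytic: bool = True
    name: str = ""

    def __post_init__(self):
        if self.n_params < 1 or self.n_outputs < 1:
            raise ValueError("n_params and n_outputs must be positive")

    def __call__(self, p):
        return self.evaluate(p)


@dataclass
class DerivativeResult:
    """Function value plus Jacobian, tagged with the engine and step used."""

    value: np.ndarray
    jacobian: np.ndarray
    engine: str
    step: float
    relative: bool = False


@dataclass
class HessianResult:
    """Symmetric Hessian of a scalar function, with the step used."""

    hessian: np.ndarray
    step: float


def _as_target(f, p) -> TargetFunction:
    if isinstance(f, TargetFunction):
        return f
    p = np.atleast_1d(np.asarray(p, dtype=float))
    out = np.atleast_1d(np.asarray(f(p)))
    return TargetFunction(f, n_params=p.size, n_outputs=out.size)


def _check_step(step):
    if not np.isfinite(step) or step <= 0:
        raise ValueError(f"step must be a positive real, got {step}")


def _output(f, p):
    return np.atleast_1d(np.asarray(f.evaluate(p)))


def complex_step_jacobian(
    f,
    p: Sequence[float],
    step: float = DEFAULT_STEP_FIRST,
    relative: bool = False,
    workers: int = 1,
) -> DerivativeResult:
    """Jacobian by the complex perturbation method.

    Column ``j`` is ``Imag f(p + iΔ_j e_j)/Δ_j`` with ``Δ_j = step``
    (absolute) or ``Δ_j = p_j·step`` (relative, falling back to the
    absolute step when ``p_j = 0``).  Per-parameter evaluations are
    independent; ``workers > 1`` runs them on a thread pool and must give
    a result identical to the serial loop.
    """
    _check_step(step)
    f = _as_target(f, p)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if not np.all(np.isfinite(p)):
        raise ValueError("parameter vector must be finite")
    if not f.analytic:
        warnings.warn(
            "complex-step differentiation of a non-analytic function; "
            "the result may be invalid",
            stacklevel=2,
        )

    value = np.real(_output(f, p.astype(complex)))
    jac = np.empty((f.n_outputs, f.n_params))

    def column(j):
        h = p[j] * step if (relative and p[j] != 0.0) else step
        pc = p.astype(complex)
        pc[j] += 1j * h
        col = np.imag(_output(f, pc)) / h
        if not np.all(np.isfinite(col)):
            raise FloatingPointError(
                f"non-finite output while perturbing parameter {j}"
            )
        return col

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            cols = list(pool.map(column, range(f.n_params)))
        for j, col in enumerate(cols):
            jac[:, j] = col
    else:
        for j in range(f.n_params):
            jac[:, j] = column(j)
    return DerivativeResult(value, jac, "complex_step", step, relative)


def complex_step_hessian(
    g, p: Sequence[float], step: float = DEFAULT_STEP_SECOND
) -> HessianResult:
    """Hessian of a scalar function by rotated complex perturbations.

    Diagonal entries use ``Imag[g(p + e^{iπ/4}Δe_j) + g(p − e^{iπ/4}Δe_j)]/Δ²``.
    Mixed partials perturb along ``e_j + e_k``, which yields
    ``∂²g/∂p_j² + ∂²g/∂p_k² + 2∂²g/∂p_j∂p_k``; the two unmixed terms are
    subtracted and the remainder halved, so diagonal entries are computed
    before any off-diagonal that consumes them.  Both triangles are
    assigned, making the result symmetric by construction.
    """
    _check_step(step)
    g = _as_target(g, p)
    if g.n_outputs != 1:
        raise ValueError("complex_step_hessian requires a scalar-valued function")
    p = np.atleast_1d(np.asarray(p, dtype=float))
    m = p.size
    dp = step * _ROT45
    hess = np.zeros((m, m))

    def paired_eval(idx):
        pc = p.astype(complex)
        for i in idx:
            pc[i] += dp
        fplus = _output(g, pc)[0]
        pc = p.astype(complex)
        for i in idx:
            pc[i] -= dp
        fminus = _output(g, pc)[0]
        out = np.imag(fplus + fminus) / step**2
        if not np.isfinite(out):
            raise FloatingPointError(f"non-finite evaluation at index pair {idx}")
        return out

    for j in range(m):
        hess[j, j] = paired_eval((j,))
    for j in range(1, m):
        for k in range(j):
            raw = paired_eval((j, k))
            hess[j, k] = hess[k, j] = (raw - hess[j, j] - hess[k, k]) / 2.0
    return HessianResult(hess, step)


def forward_difference_jacobian(f, p, step: float = 1e-6) -> DerivativeResult:
    """Jacobian by one-sided forward differences ``(f(p+Δe_j) − f(p))/Δ``."""
    _check_step(step)
    f = _as_target(f, p)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    base = _output(f, p)
    jac = np.empty((f.n_outputs, f.n_params))
    for j in range(f.n_params):
        ph = p.copy()
        ph[j] += step
        jac[:, j] = (_output(f, ph) - base) / step
    return DerivativeResult(base.copy(), jac, "forward_diff", step)


def central_difference_jacobian(f, p, step: float = 1e-6) -> DerivativeResult:
    """Jacobian by central differences ``(f(p+Δ/2·e_j) − f(p−Δ/2·e_j))/Δ``."""
    _check_step(step)
    f = _as_target(f, p)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    base = _output(f, p)
    jac = np.empty((f.n_outputs, f.n_params))
    for j in range(f.n_params):
        pp, pm = p.copy(), p.copy()
        pp[j] += step / 2.0
        pm[j] -= step / 2.0
        jac[:, j] = (_output(f, pp) - _output(f, pm)) / step
    return DerivativeResult(base.copy(), jac, "central_diff", step)


def _dual_eval(f: TargetFunction, p: np.ndarray, seeds: np.ndarray):
    """Evaluate ``f`` on dual numbers seeded with the given directions.

    ``seeds`` is (n_params, n_dirs).  Returns (value, partials matrix
    n_outputs × n_dirs).
    """
    n_dirs = seeds.shape[1]
    arg = np.empty(p.size, dtype=object)
    for i in range(p.size):
        arg[i] = Dual(p[i], seeds[i])
    out = f.evaluate(arg)
    out = np.atleast_1d(np.asarray(out, dtype=object)).ravel()
    value = np.empty(out.size)
    part = np.zeros((out.size, n_dirs))
    for i, o in enumerate(out):
        if isinstance(o, Dual):
            value[i] = o.val
            part[i] = o.der
        else:  # output constant in the parameters
            value[i] = float(o)
    return value, part


def dual_jacobian(f, p, chunk: int | None = None) -> DerivativeResult:
    """Jacobian by forward-mode dual numbers, seeding ``chunk`` unit
    directions per pass.  The result is identical (to roundoff) for any
    chunk size; larger chunks trade memory for fewer primal evaluations.
    """
    f = _as_target(f, p)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    n = p.size
    if chunk is None:
        chunk = n
    if not 1 <= chunk <= n:
        raise ValueError(f"chunk must lie in [1, {n}], got {chunk}")
    jac = np.empty((f.n_outputs, n))
    value = None
    for start in range(0, n, chunk):
        cols = range(start, min(start + chunk, n))
        seeds = np.zeros((n, len(cols)))
        for local, j in enumerate(cols):
            seeds[j, local] = 1.0
        value, part = _dual_eval(f, p, seeds)
        jac[:, list(cols)] = part
    return DerivativeResult(value, jac, "dual", 0.0)


def directional_derivative(
    f,
    p,
    v: Sequence[float],
    engine: str = "complex_step",
    step: float | None = None,
) -> np.ndarray:
    """Derivative of ``f`` at ``p`` along the direction ``v``.

    Equals ``jacobian(f, p) · v`` to engine accuracy but requires only
    one or two function evaluations regardless of the parameter count.
    """
    f = _as_target(f, p)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if v.shape != p.shape:
        raise ValueError("direction must have the same shape as the parameters")
    if np.linalg.norm(v) == 0:
        raise ValueError("direction vector must be nonzero")
    if engine == "complex_step":
        h = DEFAULT_STEP_FIRST if step is None else step
        _check_step(h)
        return np.imag(_output(f, p.astype(complex) + 1j * h * v)) / h
    if engine == "forward_diff":
        h = 1e-6 if step is None else step
        _check_step(h)
        return (_output(f, p + h * v) - _output(f, p)) / h
    if engine == "central_diff":
        h = 1e-6 if step is None else step
        _check_step(h)
        return (_output(f, p + h / 2.0 * v) - _output(f, p - h / 2.0 * v)) / h
    if engine == "dual":
        _, part = _dual_eval(f, p, v[:, None])
        return part[:, 0]
    raise ValueError(f"unknown engine {engine!r}")
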