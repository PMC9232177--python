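"""Trajectory solving and trajectory-level parameter sensitivities.

Engines
-------
``forward_ode_sensitivities``
    Integrates the augmented (variational) system: the state equations
    together with d/dt ∂x/∂β_j = (d_x f) ∂x/∂β_j + ∂f/∂β_j, all solved
    jointly.  Right-hand-side Jacobians are obtained by complex step on
    the model rhs (with an essentially exact tiny step), by central
    differences, or Jacobian-free through joint directional derivatives.
``complex_step_ode_sensitivities``
    Re-solves the ODE once per parameter with β_j + iΔ and divides the
    imaginary part of the saved states by Δ.
``second_order_ode_sensitivities``
    Treats the whole solve map β ↦ x(·, β) as the target of the rotated
    complex-step second-derivative formulas; every evaluation is a full
    ODE solve (1 + 2p + p(p−1) perturbed solves for p parameters, plus p
    first-order solves).
``adjoint_gradient``
    Continuous adjoint for a scalar functional g[x(t_n), β]: forward
    solve with dense interpolation, reverse-time costate integration
    seeded by ∂g/∂x, and accumulation of the parameter quadrature.

Complexified solves are integrated as a real system twice the size
(real and imaginary parts stacked), which keeps stiff implicit solvers
available; the imaginary components get an absolute tolerance scaled by
the perturbation Δ so the sensitivities themselves are resolved to the
requested accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .derivatives import DEFAULT_STEP_FIRST, DEFAULT_STEP_SECOND
from .models import ODEModel

__all__ = [
    "Trajectory",
    "SensitivitySolution",
    "ScalarFunctional",
    "SolverError",
    "solve_trajectory",
    "forward_ode_sensitivities",
    "complex_step_ode_sensitivities",
    "second_order_ode_sensitivities",
    "adjoint_gradient",
]

_ROT45 = (1.0 + 1.0j) / np.sqrt(2.0)
#: near-exact complex step for rhs Jacobians (no subtraction, so the
#: perturbation can sit far below machine epsilon)
_JAC_STEP = 1e-100


class SolverError(RuntimeError):
    """ODE integration failed; carries the last successful time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    """States sampled on a saveat grid."""

    times: np.ndarray
    states: np.ndarray  # n_states x n_times
    solver_rtol: float
    solver_atol: float

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_states(self) -> int:
        return self.states.shape[0]


@dataclass
class SensitivitySolution:
    """Trajectory plus first- (and optionally second-) order parameter
    derivatives ∂x_s/∂β_j(t) on the trajectory's time grid."""

    trajectory: Trajectory
    first_order: np.ndarray  # n_states x n_params x n_times
    engine: str
    second_order: np.ndarray | None = None  # n_states x n_params x n_params x n_times
    param_names: tuple = ()

    @property
    def n_params(self) -> int:
        return self.first_order.shape[1]


@dataclass
class ScalarFunctional:
    """A scalar function g(x(t_n), β) of the final state and parameters."""

    g: Callable
    description: str = ""

    def __call__(self, x_final, p):
        return self.g(x_final, p)


def _saveat_grid(tspan, saveat):
    t0, t1 = float(tspan[0]), float(tspan[1])
    if t1 <= t0:
        raise ValueError("tspan must be increasing")
    if np.isscalar(saveat):
        grid = np.arange(t0, t1 + 0.5 * float(saveat), float(saveat))
        if grid[-1] < t1 - 1e-9 * (t1 - t0):
            grid = np.append(grid, t1)
        return grid
    grid = np.asarray(saveat, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("explicit saveat grid must be strictly increasing")
    return grid


def _defaults(model, rtol, atol):
    if rtol is None:
        rtol = 1e-7 if model.stiff else 1e-5
    if atol is None:
        atol = rtol * 1e-3
    if rtol <= 0 or np.min(atol) <= 0:
        raise ValueError("rtol and atol must be positive")
    return rtol, atol


def _integrate(fun, tspan, y0, t_eval, rtol, atol, stiff, dense=False):
    method = "Radau" if stiff else "RK45"
    sol = solve_ivp(
        fun, tspan, y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        dense_output=dense,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else None
        raise SolverError(f"ODE solver failed: {sol.message}", last_time=last)
    return sol


def _integrate_complex(rhs_c, tspan, x0_c, t_eval, rtol, atol, atol_imag, stiff):
    """Integrate a complex-valued system as stacked real/imaginary parts."""
    n = len(x0_c)

    def fun(t, y):
        x = y[:n] + 1j * y[n:]
        d = np.asarray(rhs_c(t, x), dtype=complex)
        return np.concatenate([d.real, d.imag])

    y0 = np.concatenate([np.real(x0_c), np.imag(x0_c)])
    atol_vec = np.concatenate([np.full(n, atol), np.full(n, atol_imag)])
    sol = _integrate(fun, tspan, y0, t_eval, rtol, atol_vec, stiff)
    return sol.y[:n] + 1j * sol.y[n:]


def solve_trajectory(
    model: ODEModel,
    params=None,
    x0=None,
    tspan=None,
    saveat=1.0,
    rtol: float | None = None,
    atol: float | None = None,
) -> Trajectory:
    """Solve the model ODE and sample it on the saveat grid.

    ``saveat`` is either a grid spacing (default 1.0 time unit) or an
    explicit increasing grid.  Stiff models use an implicit Radau
    integrator, non-stiff models an explicit Runge–Kutta pair.
    """
    p = np.asarray(model.default_params if params is None else params, dtype=float)
    y0 = np.asarray(model.default_x0 if x0 is None else x0, dtype=float)
    tspan = model.default_tspan if tspan is None else tspan
    rtol, atol = _defaults(model, rtol, atol)
    grid = _saveat_grid(tspan, saveat)
    sol = _integrate(
        lambda t, x: np.asarray(model.rhs(x, p, t), dtype=float),
        (grid[0], grid[-1]), y0, grid, rtol, atol, model.stiff,
    )
    return Trajectory(sol.t, sol.y, rtol, float(np.min(atol)))


def _rhs_jacobians(model, x, p, t, engine="complex_step", sens=None):
    """State and parameter Jacobians of the model rhs at one point."""
    n, m = len(x), len(p)
    if engine == "complex_step":
        jx = np.empty((n, n))
        for s in range(n):
            xc = x.astype(complex)
            xc[s] += 1j * _JAC_STEP
            jx[:, s] = np.imag(model.rhs(xc, p.astype(complex), t)) / _JAC_STEP
        jp = np.empty((n, m))
        for j in range(m):
            pc = p.astype(complex)
            pc[j] += 1j * _JAC_STEP
            jp[:, j] = np.imag(model.rhs(x.astype(complex), pc, t)) / _JAC_STEP
        return jx, jp
    if engine == "central_diff":
        jx = np.empty((n, n))
        for s in range(n):
            h = 1e-6 * max(1.0, abs(x[s]))
            xp, xm = x.copy(), x.copy()
            xp[s] += h
            xm[s] -= h
            jx[:, s] = (
                np.asarray(model.rhs(xp, p, t), dtype=float)
                - np.asarray(model.rhs(xm, p, t), dtype=float)
            ) / (2 * h)
        jp = np.empty((n, m))
        for j in range(m):
            h = 1e-6 * max(1.0, abs(p[j]))
            pp, pm = p.copy(), p.copy()
            pp[j] += h
            pm[j] -= h
            jp[:, j] = (
                np.asarray(model.rhs(x, pp, t), dtype=float)
                - np.asarray(model.rhs(x, pm, t), dtype=float)
            ) / (2 * h)
        return jx, jp
    raise ValueError(f"unknown jacobian engine {engine!r}")


def forward_ode_sensitivities(
    model: ODEModel,
    params=None,
    x0=None,
    tspan=None,
    saveat=1.0,
    rtol: float | None = None,
    atol: float | None = None,
    jacobian_engine: str = "complex_step",
) -> SensitivitySolution:
    """First-order sensitivities by the forward (variational) method.

    The n·(p+1)-dimensional augmented system — states plus the
    n_states × n_params sensitivity matrix — is integrated jointly.
    Initial sensitivities are zero (the initial condition does not
    depend on the parameters).  ``jacobian_engine`` selects how the rhs
    Jacobians are formed: ``complex_step`` (default), ``central_diff``,
    or ``directional`` (Jacobian-free joint directional derivatives).
    """
    p = np.asarray(model.default_params if params is None else params, dtype=float)
    y0 = np.asarray(model.default_x0 if x0 is None else x0, dtype=float)
    tspan = model.default_tspan if tspan is None else tspan
    rtol, atol = _defaults(model, rtol, atol)
    grid = _saveat_grid(tspan, saveat)
    n, m = len(y0), len(p)

    if jacobian_engine == "directional":

        def fun(t, y):
            x = y[:n]
            sens = y[n:].reshape(n, m)
            f0 = np.asarray(model.rhs(x, p, t), dtype=float)
            dsens = np.empty((n, m))
            for j in range(m):
                # derivative of f along (S_j, e_j) in the joint (x, β) space
                xc = x.astype(complex) + 1j * _JAC_STEP * sens[:, j]
                pc = p.astype(complex)
                pc[j] += 1j * _JAC_STEP
                dsens[:, j] = np.imag(model.rhs(xc, pc, t)) / _JAC_STEP
            return np.concatenate([f0, dsens.ravel()])

    else:

        def fun(t, y):
            x = y[:n]
            sens = y[n:].reshape(n, m)
            f0 = np.asarray(model.rhs(x, p, t), dtype=float)
            jx, jp = _rhs_jacobians(model, x, p, t, jacobian_engine)
            return np.concatenate([f0, (jx @ sens + jp).ravel()])

    y_init = np.concatenate([y0, np.zeros(n * m)])
    sol = _integrate(fun, (grid[0], grid[-1]), y_init, grid, rtol, atol, model.stiff)
    states = sol.y[:n]
    first = sol.y[n:].reshape(n, m, len(grid))
    traj = Trajectory(sol.t, states, rtol, float(np.min(atol)))
    return SensitivitySolution(traj, first, "forward_ode", param_names=model.param_names)


def complex_step_ode_sensitivities(
    model: ODEModel,
    params=None,
    x0=None,
    tspan=None,
    saveat=1.0,
    step: float = DEFAULT_STEP_FIRST,
    rtol: float | None = None,
    atol: float | None = None,
    relative: bool = False,
) -> SensitivitySolution:
    """First-order sensitivities by re-solving with complex parameters.

    For each parameter j the ODE is re-solved with β_j + iΔ_j and the
    imaginary part of the saved states divided by Δ_j (Δ_j = step, or
    β_j·step under ``relative`` with absolute fallback at β_j = 0).  An
    unperturbed solve provides the trajectory.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    p = np.asarray(model.default_params if params is None else params, dtype=float)
    y0 = np.asarray(model.default_x0 if x0 is None else x0, dtype=float)
    tspan = model.default_tspan if tspan is None else tspan
    rtol, atol = _defaults(model, rtol, atol)
    grid = _saveat_grid(tspan, saveat)
    n, m = len(y0), len(p)

    base = _integrate(
        lambda t, x: np.asarray(model.rhs(x, p, t), dtype=float),
        (grid[0], grid[-1]), y0, grid, rtol, atol, model.stiff,
    )
    first = np.empty((n, m, len(grid)))
    for j in range(m):
        h = p[j] * step if (relative and p[j] != 0.0) else step
        pc = p.astype(complex)
        pc[j] += 1j * h
        try:
            states_c = _integrate_complex(
                lambda t, x: model.rhs(x, pc, t),
                (grid[0], grid[-1]), y0.astype(complex), grid,
                rtol, atol, atol * abs(h), model.stiff,
            )
        except SolverError as err:
            raise SolverError(
                f"complexified solve failed for parameter "
                f"{model.param_names[j]!r}: {err}", err.last_time,
            ) from err
        first[:, j, :] = states_c.imag / h
    traj = Trajectory(base.t, base.y, rtol, float(np.min(atol)))
    return SensitivitySolution(traj, first, "complex_step", param_names=model.param_names)


def second_order_ode_sensitivities(
    model: ODEModel,
    params=None,
    x0=None,
    tspan=None,
    saveat=1.0,
    step: float = DEFAULT_STEP_SECOND,
    first_order_step: float = DEFAULT_STEP_FIRST,
    rtol: float | None = None,
    atol: float | None = None,
) -> SensitivitySolution:
    """First- and second-order trajectory sensitivities by complex step.

    Second derivatives of the solve map use the rotated perturbation
    e^{iπ/4}Δ: pure partials from solves at β ± e^{iπ/4}Δe_j, mixed
    partials from solves at β ± e^{iπ/4}Δ(e_j + e_k) with the two pure
    terms subtracted and the remainder halved.  Pure partials are
    therefore computed before the mixed ones, and the returned array is
    symmetric in its two parameter axes by construction.

    The default solver tolerance is tightened to 1e-9 because the mixed
    formula cancels the leading O(Δ) imaginary terms, so solver noise of
    order rtol·Δ·|∂x/∂β| must sit below the Δ²·|∂²x/∂β²| signal.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if rtol is None:
        rtol = 1e-9
    sol1 = complex_step_ode_sensitivities(
        model, params, x0, tspan, saveat, first_order_step, rtol, atol,
    )
    p = np.asarray(model.default_params if params is None else params, dtype=float)
    y0 = np.asarray(model.default_x0 if x0 is None else x0, dtype=float)
    tspan = model.default_tspan if tspan is None else tspan
    rtol, atol = _defaults(model, rtol, atol)
    grid = sol1.trajectory.times
    n, m = len(y0), len(p)
    dp = step * _ROT45

    def paired_solve(idx):
        out = 0.0
        for sign in (+1.0, -1.0):
            pc = p.astype(complex)
            for i in idx:
                pc[i] += sign * dp
            states_c = _integrate_complex(
                lambda t, x: model.rhs(x, pc, t),
                (grid[0], grid[-1]), y0.astype(complex), grid,
                rtol, atol, atol, model.stiff,
            )
            out = out + states_c.imag
        return out / step**2

    second = np.empty((n, m, m, len(grid)))
    for j in range(m):
        second[:, j, j, :] = paired_solve((j,))
    for j in range(1, m):
        for k in range(j):
            raw = paired_solve((j, k))
            mixed = (raw - second[:, j, j, :] - second[:, k, k, :]) / 2.0
            second[:, j, k, :] = mixed
            second[:, k, j, :] = mixed
    return SensitivitySolution(
        sol1.trajectory, sol1.first_order, "complex_step",
        second_order=second, param_names=model.param_names,
    )


def adjoint_gradient(
    model: ODEModel,
    g,
    params=None,
    x0=None,
    tspan=None,
    rtol: float | None = None,
    atol: float | None = None,
) -> np.ndarray:
    """Gradient of a scalar functional g[x(t_n), β] by the continuous
    adjoint method.

    Solves the model forward with dense output, then integrates the
    costate λ backward from λ(t_n) = ∂g/∂x with dλ/dt = −(d_x f)ᵀλ,
    accumulating the parameter quadrature ∫ λᵀ ∂f/∂β dt alongside, and
    finally adds the explicit ∂g/∂β term.  Cost is O(n + p) solves
    rather than the O(n·p) of the forward method.
    """
    if not isinstance(g, ScalarFunctional):
        g = ScalarFunctional(g)
    p = np.asarray(model.default_params if params is None else params, dtype=float)
    y0 = np.asarray(model.default_x0 if x0 is None else x0, dtype=float)
    tspan = model.default_tspan if tspan is None else tspan
    rtol, atol = _defaults(model, rtol, atol)
    t0, t1 = float(tspan[0]), float(tspan[1])
    n, m = len(y0), len(p)

    fwd = _integrate(
        lambda t, x: np.asarray(model.rhs(x, p, t), dtype=float),
        (t0, t1), y0, None, rtol, atol, model.stiff, dense=True,
    )
    x_final = fwd.y[:, -1]

    g_val = g(x_final, p)
    if np.ndim(g_val) != 0:
        raise ValueError("functional must be scalar-valued")

    def g_grad_x(x):
        out = np.empty(n)
        for s in range(n):
            xc = x.astype(complex)
            xc[s] += 1j * _JAC_STEP
            out[s] = np.imag(g(xc, p.astype(complex))) / _JAC_STEP
        return out

    def g_grad_p():
        out = np.empty(m)
        for j in range(m):
            pc = p.astype(complex)
            pc[j] += 1j * _JAC_STEP
            out[j] = np.imag(g(x_final.astype(complex), pc)) / _JAC_STEP
        return out

    lam_T = g_grad_x(x_final)

    def reverse(t, y):
        lam = y[:n]
        x = fwd.sol(t)
        jx, jp = _rhs_jacobians(model, x, p, t)
        return np.concatenate([-jx.T @ lam, -lam @ jp])

    try:
        back = _integrate(
            reverse, (t1, t0), np.concatenate([lam_T, np.zeros(m)]),
            np.array([t1, t0]), rtol, atol, model.stiff,
        )
    except SolverError as err:
        raise SolverError(f"reverse (adjoint) solve failed: {err}", err.last_time) from err
    quad = back.y[n:, -1]
    return g_grad_p() + quad
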