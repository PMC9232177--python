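"""Birth-death-migration multitype branching processes.

Each of n nodes hosts a binary-splitting branching process with birth
rate β_i > 0 and death rate δ_i > 0; individuals migrate from node i to
node j at rate λ_ij ≥ 0.  The mean infinitesimal generator

    Ω[i, i] = β_i − δ_i − λ_i,   Ω[i, j] = λ_ij  (j ≠ i),  λ_i = Σ_{j≠i} λ_ij

drives the expected counts e^{tΩ}; the sign of its dominant eigenvalue ρ
classifies the process (subcritical ρ < 0, critical ρ = 0, supercritical
ρ > 0).  Closed-form sensitivities are available for

* the growth rate:      ∂ρ/∂θ = v (∂Ω/∂θ) w with vw = 1,
* extinction:           d_θe = (I − d_eP)⁻¹ d_θP at the minimal fixed
                        point of the progeny generating map P,
* total progeny:        d_θA = (I−F)⁻¹ (d_θF) (I−F)⁻¹ with A = (I−F)⁻¹,

and each can be cross-checked by complex-step differentiation of the
corresponding primal computation on the packed parameter vector
θ = (δ_1..δ_n, β_1..β_n, vec(λ)) (column-major vec, diagonal entries
inert).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BDMProcess",
    "EigenTriple",
    "ExtinctionResult",
    "generator_matrix",
    "mean_matrix",
    "dominant_eigen",
    "growth_rate_sensitivity",
    "progeny_gf",
    "extinction_probabilities",
    "extinction_sensitivities",
    "offspring_matrix",
    "total_progeny",
    "total_progeny_sensitivity",
    "pack_params",
    "param_labels",
]


@dataclass(frozen=True)
class BDMProcess:
    """Per-node birth/death rates and the migration-rate matrix."""

    beta: np.ndarray
    delta: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta))
        delta = np.atleast_1d(np.asarray(self.delta))
        lam = np.atleast_2d(np.asarray(self.lam))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "lam", lam)
        n = beta.size
        if delta.size != n or lam.shape != (n, n):
            raise ValueError("beta, delta and lam have inconsistent sizes")
        if not (np.all(np.isfinite(beta.real)) and np.all(np.isfinite(delta.real))
                and np.all(np.isfinite(lam.real))):
            raise ValueError("all rates must be finite")
        if np.any(np.diagonal(lam) != 0):
            raise ValueError("migration matrix must have a zero diagonal")
        if np.any(beta.real <= 0) or np.any(delta.real <= 0):
            raise ValueError("birth and death rates must be positive")
        if np.any(lam.real < 0):
            raise ValueError("migration rates must be nonnegative")

    @property
    def n(self) -> int:
        return self.beta.size

    @property
    def lam_row_sums(self) -> np.ndarray:
        return self.lam.sum(axis=1)

    def is_irreducible(self) -> bool:
        """Strong connectivity of the migration graph (trivially true for n=1)."""
        if self.n == 1:
            return True
        adj = (self.lam.real > 0).astype(int)
        ncomp, _ = connected_components(adj, directed=True, connection="strong")
        return ncomp == 1

    @classmethod
    def from_params(cls, n: int, theta: Sequence) -> "BDMProcess":
        """Unpack θ = (δ_1..δ_n, β_1..β_n, vec(λ)); the λ diagonal is
        zeroed (those slots are inert placeholders)."""
        theta = np.asarray(theta)
        if theta.size != 2 * n + n * n:
            raise ValueError(f"expected {2 * n + n * n} parameters, got {theta.size}")
        delta = theta[:n]
        beta = theta[n : 2 * n]
        lam = theta[2 * n :].reshape((n, n), order="F").copy()
        np.fill_diagonal(lam, 0)
        return cls(beta=beta, delta=delta, lam=lam)


def pack_params(proc: BDMProcess) -> np.ndarray:
    """Pack (δ, β, vec(λ)) into one vector, column-major λ."""
    return np.concatenate([proc.delta, proc.beta, proc.lam.ravel(order="F")])


def param_labels(n: int) -> list:
    """Labels aligned with :func:`pack_params` ordering."""
    out = [("delta", i) for i in range(n)] + [("beta", i) for i in range(n)]
    out += [("lambda", i, j) for j in range(n) for i in range(n)]
    return out


@dataclass
class EigenTriple:
    """Dominant eigenvalue ρ with left/right eigenvectors, vw = 1."""

    rho: float
    v: np.ndarray
    w: np.ndarray


@dataclass
class ExtinctionResult:
    """Extinction-probability vector and fixed-point iteration diagnostics."""

    e: np.ndarray
    iterations: int
    converged: bool
    residual: float


def generator_matrix(proc: BDMProcess) -> np.ndarray:
    """Mean infinitesimal generator Ω of the process."""
    is_complex = any(np.iscomplexobj(a) for a in (proc.beta, proc.delta, proc.lam))
    omega = proc.lam.astype(complex if is_complex else float)
    np.fill_diagonal(omega, proc.beta - proc.delta - proc.lam_row_sums)
    return omega


def mean_matrix(proc: BDMProcess, t: float) -> np.ndarray:
    """Expected counts e^{tΩ}: entry (i, j) is the expected number of
    individuals at node j at time t from one initial individual at i."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return expm(t * generator_matrix(proc))


def dominant_eigen(proc: BDMProcess) -> EigenTriple:
    """Dominant eigenvalue of Ω with normalized eigenvectors.

    For an irreducible process Ω is an irreducible Metzler matrix, so by
    Perron–Frobenius theory the eigenvalue of maximal real part is real
    and simple with a positive right eigenvector; w is normalized
    positive and v scaled so that v·w = 1.
    """
    if not proc.is_irreducible():
        raise ValueError(
            "migration graph is not strongly connected; analyze each "
            "communicating component separately"
        )
    omega = generator_matrix(proc)
    vals, vl, vr = _eig_full(omega)
    k = int(np.argmax(vals.real))
    rho = float(vals[k].real)
    w = vr[:, k].real
    if np.all(w <= 0):
        w = -w
    if np.any(w <= 0):
        raise RuntimeError("right eigenvector is not one-signed; eigensolve failed")
    v = vl[:, k].real
    scale = v @ w
    if scale == 0:
        raise RuntimeError("degenerate eigenvector normalization")
    v = v / scale
    return EigenTriple(rho, v, w)


def _eig_full(a):
    from scipy.linalg import eig

    vals, vl, vr = eig(a, left=True, right=True)
    return vals, vl, vr


def _structure_matrix(n: int, which) -> np.ndarray:
    """∂Ω/∂θ for one elementary rate parameter."""
    kind, idx = which[0], which[1:]
    d = np.zeros((n, n))
    if kind == "beta":
        d[idx[0], idx[0]] = 1.0
    elif kind == "delta":
        d[idx[0], idx[0]] = -1.0
    elif kind == "lambda":
        i, j = idx
        if i == j:
            return d  # inert placeholder slot
        d[i, i] = -1.0
        d[i, j] = 1.0
    else:
        raise ValueError(f"unknown parameter identifier {which!r}")
    return d


def growth_rate_sensitivity(proc: BDMProcess, which) -> float:
    """∂ρ/∂θ = v (∂Ω/∂θ) w for one rate parameter.

    ``which`` is a tuple ("beta", i), ("delta", i) or ("lambda", i, j).
    A unit increase of δ_i shifts ρ by exactly the negative of a unit
    increase of β_i, since ∂Ω/∂δ_i = −∂Ω/∂β_i.
    """
    trip = dominant_eigen(proc)
    d = _structure_matrix(proc.n, which)
    return float(trip.v @ d @ trip.w)


def progeny_gf(proc: BDMProcess, x) -> np.ndarray:
    """Progeny generating map P_i(x) = (δ_i + β_i x_i² + Σ_{j≠i} λ_ij x_j) / (β_i + δ_i + λ_i)."""
    x = np.asarray(x)
    s = proc.beta + proc.delta + proc.lam_row_sums
    return (proc.delta + proc.beta * x**2 + proc.lam @ x) / s


def extinction_probabilities(
    proc: BDMProcess, tol: float = 1e-16, maxiter: int = 500
) -> ExtinctionResult:
    """Minimal fixed point of e = P(e) by monotone functional iteration.

    Starting from e = 0 the iterates increase entrywise to the minimal
    solution: all ones when ρ ≤ 0, strictly inside (0,1)ⁿ when ρ > 0.
    Near-critical processes converge slowly; a hit of ``maxiter`` is
    reported via ``converged=False`` rather than raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.zeros(proc.n, dtype=complex if np.iscomplexobj(proc.beta) else float)
    iterations = 0
    converged = False
    for iterations in range(1, maxiter + 1):
        y = progeny_gf(proc, x)
        if np.linalg.norm(x - y) < tol:
            x = y
            converged = True
            break
        x = y
    residual = float(np.linalg.norm(x - progeny_gf(proc, x)))
    return ExtinctionResult(x, iterations, converged, residual)


def _gf_jacobian(proc: BDMProcess, e: np.ndarray) -> np.ndarray:
    """d_eP at a point e: ∂P_i/∂x_i = 2β_i e_i/s_i, ∂P_i/∂x_j = λ_ij/s_i."""
    s = proc.beta + proc.delta + proc.lam_row_sums
    jac = proc.lam / s[:, None]
    jac = jac.astype(e.dtype) if np.iscomplexobj(e) else jac.copy()
    jac[np.diag_indices(proc.n)] = 2.0 * proc.beta * e / s
    return jac


def extinction_sensitivities(proc: BDMProcess) -> np.ndarray:
    """Implicit-differentiation sensitivities d_θe of extinction.

    Differentiating e(θ) = P[e(θ), θ] gives
    d_θe = (I − d_eP)⁻¹ d_θP, valid for strictly supercritical
    processes (ρ > 0), where I − d_eP is invertible at the minimal
    fixed point.  Columns follow the :func:`pack_params` order; the
    λ-diagonal columns are identically zero.
    """
    trip = dominant_eigen(proc)
    if trip.rho <= 0:
        raise ValueError(
            f"extinction sensitivities require a supercritical process "
            f"(rho > 0); got rho = {trip.rho:.4g} where e = 1 identically"
        )
    res = extinction_probabilities(proc)
    e = res.e
    n = proc.n
    s = proc.beta + proc.delta + proc.lam_row_sums
    p_val = progeny_gf(proc, e)
    # d_thetaP columns: quotient rule; s_i contains every rate of row i
    cols = []
    for which in param_labels(n):
        col = np.zeros(n)
        kind = which[0]
        if kind == "delta":
            i = which[1]
            col[i] = (1.0 - p_val[i]) / s[i]
        elif kind == "beta":
            i = which[1]
            col[i] = (e[i] ** 2 - p_val[i]) / s[i]
        else:
            i, j = which[1], which[2]
            if i != j:
                col[i] = (e[j] - p_val[i]) / s[i]
        cols.append(col)
    dtheta_p = np.column_stack(cols)
    lhs = np.eye(n) - _gf_jacobian(proc, e)
    return np.linalg.solve(lhs, dtheta_p)


def offspring_matrix(proc: BDMProcess) -> np.ndarray:
    """Expected offspring matrix F: F_ii = 2β_i/s_i, F_ij = λ_ij/s_i."""
    s = proc.beta + proc.delta + proc.lam_row_sums
    f = proc.lam / s[:, None]
    f[np.diag_indices(proc.n)] = 2.0 * proc.beta / s
    return f


def total_progeny(proc: BDMProcess) -> np.ndarray:
    """Total-progeny matrix A = (I − F)⁻¹ for a subcritical process.

    Entry (i, j) is the expected number of type-j individuals ever
    generated by one initial type-i individual (including itself for
    j = i)."""
    f = offspring_matrix(proc)
    _check_subcritical(f)
    return np.linalg.inv(np.eye(proc.n) - f)


def _check_subcritical(f):
    radius = float(np.max(np.abs(np.linalg.eigvals(f))))
    if radius >= 1.0:
        raise ValueError(
            f"total progeny diverges: spectral radius of the offspring "
            f"matrix is {radius:.4g} >= 1 (process not subcritical)"
        )


def _offspring_matrix_sensitivity(proc: BDMProcess, which) -> np.ndarray:
    """d_θF by the quotient rule; every rate of row k also enters s_k."""
    n = proc.n
    s = proc.beta + proc.delta + proc.lam_row_sums
    f = offspring_matrix(proc)
    d = np.zeros((n, n))
    kind = which[0]
    if kind == "delta":
        k = which[1]
        d[k, :] = -f[k, :] / s[k]
    elif kind == "beta":
        k = which[1]
        d[k, :] = -f[k, :] / s[k]
        d[k, k] += 2.0 / s[k]
    elif kind == "lambda":
        k, l = which[1], which[2]
        if k == l:
            return d
        d[k, :] = -f[k, :] / s[k]
        d[k, l] += 1.0 / s[k]
    else:
        raise ValueError(f"unknown parameter identifier {which!r}")
    return d


def total_progeny_sensitivity(proc: BDMProcess, which) -> np.ndarray:
    """d_θA = (I−F)⁻¹ (d_θF) (I−F)⁻¹ for one rate parameter."""
    a = total_progeny(proc)
    return a @ _offspring_matrix_sensitivity(proc, which) @ a
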