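"""Stochastic SIR chain: mean extinction times and mean total infected.

The epidemic is a continuous-time Markov chain on (i, n) where i counts
current infectives and n = i + s counts infectives plus susceptibles out
of a closed target population of size N.  First-step analysis yields
triangular recurrences, with a = iδ and b = i(n−i)η/N:

    t_in = (1 + a·t_{i−1,n−1} + b·t_{i+1,n}) / (a + b)       mean days to
    m_in = (a·(m_{i−1,n−1} + 1) + b·m_{i+1,n}) / (a + b)     extinction /
                                                             mean ever-infected
with boundaries t_ii = Σ_{j≤i} 1/(jδ), m_ii = i, t_0n = m_0n = 0.

Parameter sensitivities come either from running the same sweep with a
complex-perturbed rate (δ + iΔ or η + iΔ) or from a hand-differentiated
tandem recurrence; the two must agree to roundoff-level accuracy.  A
Gillespie simulator and a dense first-step linear solve provide
independent validation paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "SIRChainSpec",
    "RecurrenceGrid",
    "SIRChainSensitivities",
    "SSASummary",
    "sir_mean_grids",
    "sir_mean_sensitivities",
    "sir_ssa_simulate",
    "sir_dense_means",
]

#: full (N+1)² storage above this N would exceed a desktop memory budget
_FULL_STORE_LIMIT = 4000


@dataclass(frozen=True)
class SIRChainSpec:
    """Target population size and per-day rates of the SIR chain."""

    N: int
    delta: float
    eta: float

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if self.delta <= 0:
            raise ValueError("recovery rate delta must be positive")
        if self.eta < 0:
            raise ValueError("infection rate eta must be nonnegative")


@dataclass
class RecurrenceGrid:
    """Mean grids, or just their n = N columns in streaming mode.

    ``T[i, n]`` is the mean number of days to elimination of all
    infectives from state (i, n), ``M[i, n]`` the mean number ever
    infected, both defined for 0 ≤ i ≤ n ≤ N (entries above the
    diagonal are unused and left at zero).
    """

    N: int
    t_column: np.ndarray  # T[:, N]
    m_column: np.ndarray  # M[:, N]
    T: np.ndarray | None = None
    M: np.ndarray | None = None

    @property
    def column_at_N(self):
        return self.t_column, self.m_column


@dataclass
class SIRChainSensitivities:
    """Derivative grids/columns of T and M with respect to δ and η."""

    grid: RecurrenceGrid
    engine: str
    step: float
    dT_ddelta: np.ndarray
    dT_deta: np.ndarray
    dM_ddelta: np.ndarray
    dM_deta: np.ndarray
    columns_only: bool = False


@dataclass
class SSASummary:
    """Sample means and standard errors over SSA runs."""

    runs: int
    mean_time: float
    se_time: float
    mean_infected: float
    se_infected: float
    seed: int


def _resolve_store(spec: SIRChainSpec, store: str) -> str:
    if store == "auto":
        return "full" if spec.N <= _FULL_STORE_LIMIT else "columns"
    if store == "full" and spec.N > _FULL_STORE_LIMIT:
        raise MemoryError(
            f"full grids for N={spec.N} need ~{2 * (spec.N + 1) ** 2 * 8 / 1e9:.1f} GB; "
            "use store='columns' for the streaming two-column mode"
        )
    if store not in ("full", "columns"):
        raise ValueError("store must be 'auto', 'full' or 'columns'")
    return store


def _run_sweep(N: int, delta, eta, store: str):
    """Run the recurrence sweep at (possibly complex) rates."""
    dtype = complex if (np.iscomplexobj(delta) or np.iscomplexobj(eta)) else float
    if store == "full":
        T = np.zeros((N + 1, N + 1), dtype=dtype)
        M = np.zeros((N + 1, N + 1), dtype=dtype)
        _kernels.sweep_full(N, dtype(delta), dtype(eta), T, M)
        return T, M, T[:, N].copy(), M[:, N].copy()
    bufs = [np.zeros(N + 1, dtype=dtype) for _ in range(4)]
    tcol, mcol = _kernels.sweep_columns(N, dtype(delta), dtype(eta), *bufs)
    return None, None, tcol.copy(), mcol.copy()


def sir_mean_grids(spec: SIRChainSpec, store: str = "auto") -> RecurrenceGrid:
    """Mean extinction-time and mean total-infected grids.

    ``store='full'`` keeps the whole triangular arrays for inspection
    (memory O(N²)); ``store='columns'`` streams two adjacent columns and
    returns only the n = N column, which is what the initial condition
    (i infectives, N total) reads off.  ``'auto'`` picks by N.
    """
    store = _resolve_store(spec, store)
    T, M, tcol, mcol = _run_sweep(spec.N, float(spec.delta), float(spec.eta), store)
    return RecurrenceGrid(spec.N, tcol, mcol, T, M)


def sir_mean_sensitivities(
    spec: SIRChainSpec,
    engine: str = "complex_step",
    step: float = 1e-10,
    store: str = "auto",
) -> SIRChainSensitivities:
    """Sensitivities ∂T/∂δ, ∂T/∂η, ∂M/∂δ, ∂M/∂η.

    ``engine='complex_step'`` reruns the sweep with δ + iΔ and η + iΔ
    and divides imaginary parts by Δ; ``engine='manual'`` propagates the
    analytically differentiated recurrence in the same sweep order.  The
    manual engine requires full storage (its tandem kernel is not
    streamed); the complex engine supports both modes.
    """
    store = _resolve_store(spec, store)
    if engine == "complex_step":
        if step <= 0:
            raise ValueError("step must be positive")
        T0, M0, t0, m0 = _run_sweep(spec.N, float(spec.delta), float(spec.eta), store)
        Td_, Md_, td, md = _run_sweep(spec.N, spec.delta + 1j * step, float(spec.eta), store)
        Te_, Me_, te, me = _run_sweep(spec.N, float(spec.delta), spec.eta + 1j * step, store)
        grid = RecurrenceGrid(spec.N, t0, m0, T0, M0)
        if store == "full":
            return SIRChainSensitivities(
                grid, engine, step,
                Td_.imag / step, Te_.imag / step, Md_.imag / step, Me_.imag / step,
            )
        return SIRChainSensitivities(
            grid, engine, step,
            td.imag / step, te.imag / step, md.imag / step, me.imag / step,
            columns_only=True,
        )
    if engine == "manual":
        if store == "columns":
            raise ValueError(
                "the manual tandem engine requires store='full'; use the "
                "complex_step engine for streaming sensitivities"
            )
        n1 = spec.N + 1
        T, M, Td, Te, Md, Me = (np.zeros((n1, n1)) for _ in range(6))
        _kernels.sweep_full_tandem(
            spec.N, float(spec.delta), float(spec.eta), T, M, Td, Te, Md, Me
        )
        grid = RecurrenceGrid(spec.N, T[:, spec.N].copy(), M[:, spec.N].copy(), T, M)
        return SIRChainSensitivities(grid, engine, 0.0, Td, Te, Md, Me)
    raise ValueError("engine must be 'complex_step' or 'manual'")


def sir_ssa_simulate(
    s0: int, i0: int, delta: float, eta: float, runs: int, seed: int
) -> SSASummary:
    """Exact stochastic simulation of the SIR chain.

    Direct-method Gillespie simulation with infection rate i(n−i)η/N and
    recovery rate iδ, N = s0 + i0.  Runs until extinction of infectives;
    reproducible under ``seed``.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs to estimate standard errors")
    if delta <= 0 or eta < 0:
        raise ValueError("rates must satisfy delta > 0 and eta >= 0")
    if i0 < 1 or s0 < 0:
        raise ValueError("need i0 >= 1 and s0 >= 0")
    times, infected = _kernels.ssa_runs(
        int(s0), int(i0), float(delta), float(eta), int(runs), int(seed) % 2**32
    )
    return SSASummary(
        runs=runs,
        mean_time=float(np.mean(times)),
        se_time=float(np.std(times, ddof=1) / np.sqrt(runs)),
        mean_infected=float(np.mean(infected)),
        se_infected=float(np.std(infected, ddof=1) / np.sqrt(runs)),
        seed=seed,
    )


def sir_dense_means(spec: SIRChainSpec, max_size: int = 60) -> RecurrenceGrid:
    """Mean grids by densely solving the first-step linear system.

    Builds one linear equation per reachable state (i, n), 1 ≤ i ≤ n ≤ N,
    directly from the chain's jump probabilities and solves it with a
    dense factorization.  This is an independent route to the same
    quantities as :func:`sir_mean_grids` (the infection rate b vanishes
    at i = n, so no special boundary casing is needed) and is intended
    for validation at small N.
    """
    N = spec.N
    if N > max_size:
        raise ValueError(f"dense oracle is O(N^4) in memory; N={N} exceeds {max_size}")
    states = [(i, n) for n in range(1, N + 1) for i in range(1, n + 1)]
    index = {sn: k for k, sn in enumerate(states)}
    m = len(states)
    A = np.eye(m)
    rhs = np.zeros((m, 2))
    for (i, n), k in index.items():
        a = i * spec.delta
        b = i * (n - i) * spec.eta / N
        tot = a + b
        # T: t = 1/tot + (a/tot) t_down + (b/tot) t_up
        # M: m = (a/tot)(m_down + 1) + (b/tot) m_up
        rhs[k, 0] = 1.0 / tot
        rhs[k, 1] = a / tot
        if i - 1 >= 1:
            A[k, index[(i - 1, n - 1)]] -= a / tot
        if b > 0:
            A[k, index[(i + 1, n)]] -= b / tot
    sol = np.linalg.solve(A, rhs)
    t_flat, m_flat = sol[:, 0], sol[:, 1]
    T = np.zeros((N + 1, N + 1))
    M = np.zeros((N + 1, N + 1))
    for (i, n), k in index.items():
        T[i, n] = t_flat[k]
        M[i, n] = m_flat[k]
    return RecurrenceGrid(N, T[:, N].copy(), M[:, N].copy(), T, M)
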