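"""Numba-compiled inner loops for the stochastic SIR chain.

The triangular mean recurrences touch O(N²) cells, so the sweeps are
JIT-compiled.  Each kernel is written generically and specializes for
float64 and complex128 arguments, which lets the complex-perturbation
sensitivity engine reuse the exact same sweep.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit
def sweep_full(N, delta, eta, T, M):
    """Fill the full (N+1)×(N+1) grids T[i, n], M[i, n] in place.

    Sweep order: n ascending, i descending from n to 1, because the
    in-column dependence runs from i+1 down to i.  Row i = 0 stays at
    the boundary value 0.
    """
    for n in range(1, N + 1):
        for i in range(n, 0, -1):
            a = i * delta
            if i == n:
                T[i, n] = T[i - 1, n - 1] + 1.0 / a
                M[i, n] = i
            else:
                b = i * (n - i) * eta / N
                c = 1.0 / (a + b)
                T[i, n] = c * (1.0 + a * T[i - 1, n - 1] + b * T[i + 1, n])
                M[i, n] = c * (a * (M[i - 1, n - 1] + 1.0) + b * M[i + 1, n])


@njit
def sweep_columns(N, delta, eta, tp, tc, mp, mc):
    """Streaming sweep keeping only two adjacent n-columns.

    ``tp``/``mp`` hold column n−1 and ``tc``/``mc`` column n; buffers
    are swapped after each column.  Returns the n = N columns.  Memory
    is O(N) instead of O(N²)."""
    for n in range(1, N + 1):
        for i in range(n, 0, -1):
            a = i * delta
            if i == n:
                tc[i] = tp[i - 1] + 1.0 / a
                mc[i] = i
            else:
                b = i * (n - i) * eta / N
                c = 1.0 / (a + b)
                tc[i] = c * (1.0 + a * tp[i - 1] + b * tc[i + 1])
                mc[i] = c * (a * (mp[i - 1] + 1.0) + b * mc[i + 1])
        tp, tc = tc, tp
        mp, mc = mc, mp
    return tp, mp


@njit
def sweep_full_tandem(N, delta, eta, T, M, Td, Te, Md, Me):
    """Primal grids plus hand-differentiated derivative grids.

    Propagates ∂T/∂δ (Td), ∂T/∂η (Te), ∂M/∂δ (Md), ∂M/∂η (Me) in
    tandem with the primal sweep by the quotient rule on a = iδ,
    b = i(n−i)η/N and c = 1/(a+b).
    """
    for n in range(1, N + 1):
        for i in range(n, 0, -1):
            a = i * delta
            if i == n:
                T[i, n] = T[i - 1, n - 1] + 1.0 / a
                M[i, n] = i
                # d(1/a)/ddelta = -i/a^2 = -1/(i*delta^2)
                Td[i, n] = Td[i - 1, n - 1] - 1.0 / (i * delta * delta)
                Te[i, n] = Te[i - 1, n - 1]
                Md[i, n] = 0.0
                Me[i, n] = 0.0
            else:
                b = i * (n - i) * eta / N
                c = 1.0 / (a + b)
                da = float(i)          # da/ddelta
                db = i * (n - i) / N   # db/deta
                dc_dd = -da * c * c
                dc_de = -db * c * c
                t1 = T[i - 1, n - 1]
                t2 = T[i + 1, n]
                s = 1.0 + a * t1 + b * t2
                T[i, n] = c * s
                Td[i, n] = dc_dd * s + c * (da * t1 + a * Td[i - 1, n - 1] + b * Td[i + 1, n])
                Te[i, n] = dc_de * s + c * (db * t2 + a * Te[i - 1, n - 1] + b * Te[i + 1, n])
                m1 = M[i - 1, n - 1] + 1.0
                m2 = M[i + 1, n]
                r = a * m1 + b * m2
                M[i, n] = c * r
                Md[i, n] = dc_dd * r + c * (da * m1 + a * Md[i - 1, n - 1] + b * Md[i + 1, n])
                Me[i, n] = dc_de * r + c * (db * m2 + a * Me[i - 1, n - 1] + b * Me[i + 1, n])


@njit
def ssa_runs(s0, i0, delta, eta, runs, seed):
    """Exact direct-method SSA for the stochastic SIR chain.

    Events from state (i, n): infection at rate i(n−i)η/N (i → i+1) and
    recovery at rate iδ (i → i−1, n → n−1), with N = s0 + i0 fixed.
    Each run proceeds until i = 0; returns per-run extinction times and
    total ever-infected counts.
    """
    np.random.seed(seed)
    N = s0 + i0
    times = np.empty(runs)
    infected = np.empty(runs)
    for r in range(runs):
        i = i0
        n = s0 + i0
        t = 0.0
        total = i0
        while i > 0:
            a = i * delta
            b = i * (n - i) * eta / N
            rate = a + b
            t += np.random.exponential(1.0 / rate)
            if np.random.random() * rate < b:
                i += 1
                total += 1
            else:
                i -= 1
                n -= 1
        times[r] = t
        infected[r] = total
    return times, infected
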