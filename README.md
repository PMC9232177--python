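# diffsens

Differential sensitivity analysis for deterministic and stochastic
biological models: how much does a model's output move when each rate
parameter moves?

The package is aimed at modelers in oncology, epidemiology and
population dynamics who need gradients (and Hessians) of model outputs
with respect to parameters — for parameter estimation, experiment
design, intervention ranking, or cheap prediction of nearby
trajectories — without deriving them by hand.

## What it computes

**Derivative engines** for any analytic map f(p):

* complex step, `∂f/∂p_j ≈ Imag f(p + iΔe_j)/Δ` — cancellation-free,
  accurate to roundoff at Δ ≈ 1e-12;
* a rotated-step (`e^{iπ/4}Δ`) complex formula for full Hessians
  including mixed partials, O(Δ⁴) accurate;
* forward/central finite differences and a minimal dual-number
  forward-mode engine with chunked seeding, as baselines and
  cross-checks.

**ODE trajectory sensitivities** `∂x_s(t)/∂β_j` for bundled models —
CARRGO tumor–immune dynamics, the deterministic SIR epidemic, the stiff
Robertson system — or any user-defined model, via the forward
(variational) equations, per-parameter complex-step re-solves,
second-order complex-step solves, and a continuous adjoint for scalar
functionals g[x(T), β].

**Taylor prediction** of perturbed trajectories,
`x(β+v) ≈ x + (∂x/∂β)v + ½vᵀ(∂²x/∂β²)v`, with normalized
prediction-error norms err1/err2.

**Stochastic SIR chain**: triangular first-step recurrences for the
mean days to extinction T[i,n] and mean total ever infected M[i,n],
with a = iδ, b = i(n−i)η/N:

    T[i,n] = (1 + a·T[i−1,n−1] + b·T[i+1,n]) / (a+b)
    M[i,n] = (a·(M[i−1,n−1]+1) + b·M[i+1,n]) / (a+b)

solved by a numba-compiled sweep (streaming O(N) memory mode for
population scales like N = 34001), their δ- and η-sensitivities by
complex step or a hand-differentiated tandem recurrence, and a seeded
Gillespie simulator for validation.

**Birth-death-migration branching processes**: mean generator Ω and
e^{tΩ}, dominant growth rate ρ with its eigenvector sensitivity formula
∂ρ/∂θ = v(∂Ω/∂θ)w, extinction probabilities by monotone fixed-point
iteration of e = P(e) with implicit-differentiation sensitivities
(I − d_eP)⁻¹d_θP, and the total-progeny matrix A = (I−F)⁻¹ with
d_θA = A(d_θF)A.

## Worked example

Sensitivities of the susceptible compartment of the SIR model
(η = 0.7194, δ = 0.5025, S₀ = 3.4e8, I₀ = 100) by the complex-step
engine:

```python
import numpy as np
import diffsens as ds

model = ds.sir_model()
sol = ds.complex_step_ode_sensitivities(model, tspan=(0.0, 120.0))
t = sol.trajectory.times
k = np.argmin(np.abs(t - 60.0))
print(f"S(60)      = {sol.trajectory.states[0, k]:.6g}")
print(f"dS/deta    = {sol.first_order[0, 0, k]:.6g}")
print(f"dS/ddelta  = {sol.first_order[0, 1, k]:.6g}")
```

prints

```
S(60)      = 2.62457e+08
dS/deta    = -2.42638e+09
dS/ddelta  = 2.40833e+09
```

— at day 60 about 77% of the population is still susceptible; raising
the infection rate η by 0.01 would remove roughly 2.4e7 more people
from the susceptible pool, and raising the recovery rate δ by the same
amount would keep almost exactly as many in it. The near-antisymmetry
of the two sensitivities is a structural feature of the SIR model near
its η/δ threshold.

The same machinery runs from the command line; for the stochastic
chain with one initial infective in a population of 1000:

```
$ diffsens sir-chain --N 1000 --sensitivities complex --out out/
T[1,N]=15.9761 days  M[1,N]=157.664 people
```

and `out/grid.csv` holds the full (i, n) grids of T, M and their four
parameter derivatives. `diffsens diff-check --function decay` prints a
per-engine error table against the analytic derivative of exponential
decay:

```
function       engine  max_abs_error
   decay complex_step   1.110223e-16
   decay forward_diff   4.559428e-06
   decay central_diff   1.031830e-10
   decay         dual   1.110223e-16
```

Other subcommands: `ode-sens` (trajectory sensitivities for
carrgo/sir/rober), `predict` (first- vs second-order Taylor prediction
under seeded random perturbations), `branching` (growth rate,
extinction, total progeny and their sensitivities).

## Documentation

`docs/methods.md` describes the mathematical formulation, the numerical
choices (step sizes, tolerances, storage modes, gating of the implicit
formulas) and known limitations.
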