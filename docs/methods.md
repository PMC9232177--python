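# Methods

This note records the models, numerical choices and known limitations
behind `diffsens`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Derivative engines

For an analytic map f: ℝᵖ → ℝᵐ the complex-step approximation

    ∂f/∂p_j ≈ Imag f(p + iΔ e_j) / Δ

has O(Δ²) truncation error and no subtractive cancellation, so Δ can sit
near machine precision. Default Δ = 1e-12 (first order). A relative
variant perturbs by p_j·Δ for badly scaled parameters and falls back to
the absolute step at p_j = 0 (the zero-parameter case is our choice; any
fixed fallback is defensible, and the absolute step keeps the column
well-defined).

Second derivatives use the rotated step e^{iπ/4}Δ:

    ∂²g/∂p_j² ≈ Imag[g(p + e^{iπ/4}Δe_j) + g(p − e^{iπ/4}Δe_j)] / Δ²

with O(Δ⁴) truncation. Perturbing along e_j + e_k instead yields
∂²g/∂p_j² + ∂²g/∂p_k² + 2∂²g/∂p_j∂p_k, from which the mixed partial
follows by subtracting the two pure terms and halving — so the diagonal
is always computed first, and the returned matrix is symmetric by
construction. Unlike the first-order formula this one cancels the O(Δ)
imaginary terms subtractively, reintroducing roundoff of order ε/Δ²;
the default Δ = 1e-4 balances that against truncation (the usable band
is roughly 1e-3 … 1e-5, where the test oracles measure relative errors
below 1e-9 on exp/sin compositions).

Finite differences (forward and central) are provided as baselines; the
measured error curves behave as theory predicts (central differences
have a U-shaped error with an interior optimum near Δ ≈ 1e-6, and blow
up by cancellation at Δ = 1e-12 where the complex step is still at the
roundoff floor).

The dual-number engine carries a value plus a vector of partials
through +, −, ×, ÷, powers, exp, log, sin, cos and sqrt, seeding up to
`chunk` unit directions per pass; results are bitwise independent of
the chunk size. Only first-order partials are carried — the complex-step
Hessian is the second-order engine — and unsupported primitives (abs,
floor division, …) raise an error naming the operation rather than
silently producing a wrong derivative.

## ODE trajectory sensitivities

Differentiating dx/dt = f(x, β) in β and exchanging derivative order
gives the variational system

    d/dt ∂x/∂β_j = (d_x f) ∂x/∂β_j + ∂f/∂β_j,   ∂x/∂β_j(0) = 0,

integrated jointly with the states (`forward_ode_sensitivities`). The
rhs Jacobians are formed per step by complex step with Δ = 1e-100 —
no subtraction occurs, so the step can sit far below machine epsilon
and the Jacobian is exact to roundoff — by central differences, or
Jacobian-free via joint directional derivatives (useful when n·p grows).

`complex_step_ode_sensitivities` instead re-solves the ODE once per
parameter with β_j + iΔ. Complexified systems are integrated as stacked
real/imaginary real systems of twice the size, which keeps implicit
stiff solvers available (scipy's Radau does not accept complex state).
The imaginary components have magnitude Δ·|∂x/∂β|, so they receive an
absolute tolerance scaled by Δ while the real components keep the
user's atol; the relative accuracy of the extracted sensitivities is
then governed by rtol alone. Without this scaling the solver would
treat the imaginary parts as numerically zero at Δ = 1e-12.

Second-order trajectory sensitivities apply the rotated-step formulas
to the whole solve map: each function evaluation is a full ODE solve
(1 unperturbed + 2p pure + p(p−1) mixed, plus p first-order solves).
The default solver tolerance tightens to rtol = 1e-9 here because the
mixed formula cancels O(Δ) imaginary terms: solver noise of order
rtol·Δ·|∂x/∂β| must stay below the Δ²·|∂²x/∂β²| signal.

The adjoint engine computes ∇_β g[x(t_n), β] for scalar functionals:
forward solve with dense interpolation, then reverse-time integration
of dλ/dt = −(d_x f)ᵀλ from λ(t_n) = ∂g/∂x with the quadrature
∫ λᵀ(∂f/∂β)dt accumulated as p extra components, plus the explicit
∂g/∂β term. This is the standard continuous adjoint; it is validated
against the forward method (closed-form gradient of exponential decay,
and agreement within 1e-3 relative on the tumor–immune model at
rtol = 1e-8). Discrete (solver-differentiating) adjoints and
checkpointing are out of scope, as are sensitivities with respect to
initial conditions.

Solver defaults: explicit RK45 for non-stiff models at rtol = 1e-5,
implicit Radau for stiff ones at rtol = 1e-7, atol = rtol·1e-3, output
sampled every 1.0 time unit. All are per-call overridable.

## Bundled models

* **CARRGO** (tumor–immune predator–prey): dx/dt = ρx(1 − y/γ) − κ₁xy,
  dy/dt = κ₂xy − θy, with κ₁ = 6e-9, κ₂ = 3e-11 /(day·cell),
  θ = 1e-6 /day, ρ = 6e-2 /day, γ = 1e9 cells, x₀ = 1.25e4,
  y₀ = 6.25e2 cells, 1000 days. The logistic term divides the
  *predator* count by γ in this formulation; we implement it exactly as
  such and expose `logistic_in_x=True` for the conventional prey-crowding
  form. Note the model's long-time behaviour: the cancer compartment is
  driven to ~1e-14 by day 1000, so end-time sensitivities of x are
  numerically zero and time-resolved sensitivities are the informative
  output (sensitivity to γ changes sign over time; the ρ-sensitivity
  magnitude peaks near day 240 in our solves).
* **SIR**: dS = −ηIS/N, dI = ηIS/N − δI, dR = δI with η = 0.7194,
  δ = 0.5025 /day, N = 3.4e8 fixed (not a rate; opt-in as a third
  parameter), S₀ = 3.4e8, I₀ = 100, one year.
* **ROBER** (Robertson kinetics): the classic stiff three-species
  system with rates (4e-2, 3e7, 1e4) from x₀ = (1, 0, 0); mass
  conservation x₁+x₂+x₃ = 1 transfers to every sensitivity sheet
  (component sums of ∂x/∂β_j vanish), which the tests assert.

## Taylor prediction and error norms

Given first- and second-order sensitivities, a perturbed trajectory is
predicted as x + (∂x/∂β)v and x + (∂x/∂β)v + ½vᵀ(∂²x/∂β²)v. The
experiment driver multiplies each parameter by (1 + U_i),
U_i ~ Uniform(−m, m), seeded. Prediction error is the Frobenius norm of
(resolved − predicted) divided by the entry count for vector outputs
and its square for matrix outputs; a sqrt-of-count convention is
selectable since only the relative comparison between expansion orders
matters. At the small-epidemic demonstration conditions (S₀ = 1000,
I₀ = 10, 100 days, 25% perturbations) the second-order error is about
an order of magnitude below first order, and the err2/err1 ratio
shrinks roughly linearly as the perturbation magnitude drops — the
expected O(‖v‖³) vs O(‖v‖²) residual scaling.

## Stochastic SIR chain

States (i, n) track current infectives and infectives-plus-susceptibles
in a closed population of N. First-step analysis gives triangular
recurrences for the mean days to extinction T and mean ever-infected M
(see the module docstring for the formulas), swept with n ascending and
i descending — the order is forced because T[i+1, n] must precede
T[i, n]. Boundary values: T[i,i] is the harmonic sum Σ_{j≤i} 1/(jδ)
(pure death chain), M[i,i] = i, and row i = 0 is zero.

The sweep is numba-compiled and written generically so the identical
kernel runs on float64 (primal) and complex128 (complex-step
sensitivities). Full (N+1)² storage is kept for N ≤ 4000 for
inspectability; beyond that a streaming mode keeps two adjacent columns
(O(N) memory) and returns the n = N column, which is what the standard
initial condition reads. The N = 34001 full-scale run (one infective in
a population of 34001 at η = 0.7194, δ = 0.5025) takes a few seconds
and yields T[1,N] = 27.924 days, M[1,N] = 5484.5 people.

Sensitivities come from (a) the complex-step sweep or (b) a manual
tandem sweep propagating the quotient-rule-differentiated recurrence;
the two agree entrywise to ~1e-13 relative at N = 100. The manual
engine is implemented for full storage only; the complex engine covers
the streaming regime. Two independent validation paths exist: a dense
first-step linear solve (exact to 1e-12 at small N — note the infection
rate b vanishes automatically at i = n, so the linear system needs no
boundary special-casing) and a direct-method Gillespie simulator
(numba, seeded) whose 100-run means fall within three standard errors
of the recurrence values at full scale.

The mean extinction time is *not* monotone in the number of initial
infectives at these rates: T[i, N] rises at small i but peaks and then
declines slowly, because many initial infectives deplete susceptibles
faster and shorten the epidemic. M[i, N] is monotone. Tests assert
exactly this structure rather than a blanket monotonicity.

## Branching processes

For the birth-death-migration process the generator Ω, offspring matrix
F and progeny generating map P are formed in closed form from the rates
(see the module docstring). Analytic sensitivities:

* growth rate: ∂ρ/∂θ = v(∂Ω/∂θ)w with v·w = 1, where ∂Ω/∂θ is the
  elementary structure matrix of the rate (for migration rates it has
  −1 on the diagonal and +1 at (i, j)); ∂ρ/∂δ_i = −∂ρ/∂β_i exactly;
* extinction: d_θe = (I − d_eP)⁻¹ d_θP by implicit differentiation at
  the minimal fixed point, gated on strict supercriticality (ρ > 0)
  where the inverse exists;
* total progeny: d_θA = A(d_θF)A with A = (I − F)⁻¹, gated on spectral
  radius of F below one.

The dominant eigenvalue is taken as the eigenvalue of maximal real part
— real and simple for irreducible Metzler matrices (Perron–Frobenius) —
with the right eigenvector normalized positive before imposing v·w = 1;
reducible migration graphs are rejected with a pointer to per-component
analysis. Extinction probabilities iterate e ← P(e) from 0 (monotone,
bounded, converging to the minimal fixed point) with defaults of 500
iterations and a 1e-16 stopping norm; hitting the cap reports
`converged=False` instead of raising, since near-critical processes
converge slowly.

Parameters pack as θ = (δ₁..δ_n, β₁..β_n, vec(λ)) with column-major
vec; the λ-diagonal slots are inert placeholders whose derivatives are
identically zero, keeping packed indices aligned with the matrix
layout. Every analytic sensitivity is cross-checked against complex-step
differentiation of its primal computation on 50 random fixtures
(agreement ~1e-8 relative, far inside the 1e-6 gate), and the
implicit-differentiation result also equals the limit of differentiating
the fixed-point iteration itself.

Random fixtures draw β ∈ [0.05, 0.16], δ ∈ [0.05, 0.19],
λ ∈ [3e-4, 4.6e-4] uniformly; criticality modes override δ = β ± 0.03,
which with these migration scales pins the sign of ρ.

## What the synthetic inputs do and do not emulate

There is no external data anywhere: inputs are the bundled model
constants, seeded uniform parameter perturbations, and seeded random
rate draws. These exercise every code path at realistic magnitudes
(rates spanning 6e-9 … 3e7, populations 1e3 … 3.4e8) but contain no
measurement noise, model misspecification or parameter correlation —
passing tests demonstrate numerical correctness of the sensitivity
machinery, not that any model fits data.

## Numerical choices and limitations

* Problem sizes in the tests and the acceptance script are the study
  conditions themselves (N = 34001 chain, 100 SSA runs, 50 random
  branching fixtures, 1000-day trajectories); nothing is scaled down.
* Complex-step cross-checks use Δ = 1e-10 against analytic formulas at
  a 1e-6 relative gate with a 1e-9 absolute floor for near-zero entries.
* Degenerate inputs: zero direction vectors, non-increasing time spans,
  nonpositive steps and tolerances, vector-valued functionals where a
  scalar is required, reducible migration graphs, and sub/supercritical
  gate violations all raise with specific messages; solver failures
  carry the last successful time.
* Higher-order expansions, reverse-mode AD, Richardson extrapolation,
  time-dependent rates, extinction-time distributions beyond the mean,
  and general (non-binary-splitting) offspring laws are out of scope.
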