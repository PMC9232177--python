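"""Bundled ODE models: CARRGO tumor–immune dynamics, the deterministic
SIR epidemic, and the stiff Robertson (ROBER) reaction system.

Each model carries its customary default parameters, initial conditions
and time span, and a right-hand side written with analytic elementary
operations only, so all derivative engines (complex step, dual numbers,
finite differences) apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["ODEModel", "carrgo_model", "sir_model", "rober_model", "get_model", "MODEL_NAMES"]


@dataclass(frozen=True)
class ODEModel:
    """A named dynamical system dx/dt = f(x, p, t).

    ``rhs`` accepts real, complex or dual-number states and parameters
    and returns the state derivative with matching carrier type.
    """

    name: str
    state_names: tuple
    param_names: tuple
    rhs: Callable
    default_params: np.ndarray
    default_x0: np.ndarray
    default_tspan: tuple
    stiff: bool = False

    def __post_init__(self):
        if len(self.default_params) != len(self.param_names):
            raise ValueError("default_params length must match param_names")
        if len(self.default_x0) != len(self.state_names):
            raise ValueError("default_x0 length must match state_names")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "state_names": list(self.state_names),
            "param_names": list(self.param_names),
            "default_params": [float(v) for v in self.default_params],
            "default_x0": [float(v) for v in self.default_x0],
            "default_tspan": list(self.default_tspan),
            "stiff": self.stiff,
        }


def _stack(parts):
    """Stack rhs components, keeping complex/object carriers intact."""
    if any(isinstance(v, complex) or (hasattr(v, "imag") and np.iscomplexobj(v)) for v in parts):
        return np.array(parts, dtype=complex)
    if any(not isinstance(v, (int, float, np.integer, np.floating)) for v in parts):
        return np.array(parts, dtype=object)
    return np.array(parts, dtype=float)


def carrgo_model(logistic_in_x: bool = False) -> ODEModel:
    """CARRGO predator–prey model of CAR T-cell therapy.

    Cancer cells ``x`` act as prey with logistic growth and CAR T-cells
    ``y`` as predators:

        dx/dt = ρ x (1 − y/γ) − κ₁ x y
        dy/dt = κ₂ x y − θ y

    The logistic term divides ``y`` by the carrying capacity γ in the
    reference formulation used here; ``logistic_in_x=True`` selects the
    conventional ``(1 − x/γ)`` variant instead.  Parameters are per day
    (rates) and cells (γ).
    """

    def rhs(x, p, t):
        kappa1, kappa2, theta, rho, gamma = p[0], p[1], p[2], p[3], p[4]
        crowding = x[0] if logistic_in_x else x[1]
        dx = rho * x[0] * (1 - crowding / gamma) - kappa1 * x[0] * x[1]
        dy = kappa2 * x[0] * x[1] - theta * x[1]
        return _stack([dx, dy])

    return ODEModel(
        name="carrgo",
        state_names=("x", "y"),
        param_names=("kappa1", "kappa2", "theta", "rho", "gamma"),
        rhs=rhs,
        default_params=np.array([6.0e-9, 3.0e-11, 1.0e-6, 6.0e-2, 1.0e9]),
        default_x0=np.array([1.25e4, 6.25e2]),
        default_tspan=(0.0, 1000.0),
    )


def sir_model(population: float = 3.4e8, population_as_param: bool = False) -> ODEModel:
    """Deterministic SIR epidemic model.

        dS/dt = −η I S / N,  dI/dt = η I S / N − δ I,  dR/dt = δ I

    ``η`` is the daily infection rate per encounter and ``δ`` the daily
    recovery rate per person.  The total population ``N`` is a fixed
    constant by default (it is not an epidemiological rate); pass
    ``population_as_param=True`` to expose it as a third sensitivity
    parameter.
    """

    if population_as_param:

        def rhs(x, p, t):
            eta, delta, N = p[0], p[1], p[2]
            infection = eta * x[1] * x[0] / N
            return _stack([-infection, infection - delta * x[1], delta * x[1]])

        param_names = ("eta", "delta", "N")
        defaults = np.array([0.7194, 0.5025, population])
    else:

        def rhs(x, p, t):
            eta, delta = p[0], p[1]
            infection = eta * x[1] * x[0] / population
            return _stack([-infection, infection - delta * x[1], delta * x[1]])

        param_names = ("eta", "delta")
        defaults = np.array([0.7194, 0.5025])

    return ODEModel(
        name="sir",
        state_names=("S", "I", "R"),
        param_names=param_names,
        rhs=rhs,
        default_params=defaults,
        default_x0=np.array([population, 100.0, 0.0]),
        default_tspan=(0.0, 365.0),
    )


def rober_model() -> ODEModel:
    """Robertson stiff chemical kinetics benchmark.

        dx₁/dt = −p₁x₁ + p₃x₂x₃
        dx₂/dt =  p₁x₁ − p₃x₂x₃ − p₂x₂²
        dx₃/dt =  p₂x₂²

    The rate constants span nine orders of magnitude, making the system
    severely stiff; total mass x₁+x₂+x₃ is conserved.
    """

    def rhs(x, p, t):
        p1, p2, p3 = p[0], p[1], p[2]
        r1 = p1 * x[0]
        r2 = p2 * x[1] * x[1]
        r3 = p3 * x[1] * x[2]
        return _stack([-r1 + r3, r1 - r3 - r2, r2])

    return ODEModel(
        name="rober",
        state_names=("x1", "x2", "x3"),
        param_names=("p1", "p2", "p3"),
        rhs=rhs,
        default_params=np.array([4.0e-2, 3.0e7, 1.0e4]),
        default_x0=np.array([1.0, 0.0, 0.0]),
        default_tspan=(0.0, 1000.0),
        stiff=True,
    )


_REGISTRY = {"carrgo": carrgo_model, "sir": sir_model, "rober": rober_model}
MODEL_NAMES = tuple(sorted(_REGISTRY))


def get_model(name: str, **kwargs) -> ODEModel:
    """Look up a bundled model by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available models: {', '.join(MODEL_NAMES)}"
        ) from None
    return factory(**kwargs)
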