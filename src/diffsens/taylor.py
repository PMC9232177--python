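"""Taylor prediction of perturbed trajectories and prediction-error norms.

Given a trajectory x(t, β) and its parameter sensitivities, the first-
and second-order expansions

    x(t, β + v) ≈ x + (∂x/∂β)·v
    x(t, β + v) ≈ x + (∂x/∂β)·v + ½ vᵀ(∂²x/∂β²)v

predict the trajectory at displaced parameters without re-solving.  The
prediction error err1/err2 is the Euclidean (Frobenius) norm of the
difference against a re-solved trajectory, normalized by the entry count
(vectors) or its square (matrices); a sqrt-of-count convention is also
selectable since the normalization only rescales comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .odesens import SensitivitySolution

__all__ = [
    "PredictionReport",
    "predict_first_order",
    "predict_second_order",
    "prediction_error",
    "perturb_params",
]


@dataclass
class PredictionReport:
    """Normalized prediction error for one expansion order."""

    order: int
    perturbation: np.ndarray
    err: float
    raw_norm: float
    normalization: float

    def __post_init__(self):
        if self.err < 0:
            raise ValueError("err must be nonnegative")


def predict_first_order(sol: SensitivitySolution, v) -> np.ndarray:
    """First-order Taylor prediction of the trajectory at β + v."""
    v = np.asarray(v, dtype=float)
    if v.shape != (sol.n_params,):
        raise ValueError(
            f"displacement length {v.size} does not match {sol.n_params} parameters"
        )
    return sol.trajectory.states + np.einsum("spt,p->st", sol.first_order, v)


def predict_second_order(sol: SensitivitySolution, v) -> np.ndarray:
    """Second-order Taylor prediction of the trajectory at β + v."""
    if sol.second_order is None:
        raise ValueError(
            "sensitivity solution has no second-order derivatives; "
            "compute them with second_order_ode_sensitivities"
        )
    first = predict_first_order(sol, v)
    v = np.asarray(v, dtype=float)
    return first + 0.5 * np.einsum("spqt,p,q->st", sol.second_order, v, v)


def prediction_error(
    actual, predicted, kind: str = "matrix", order: int = 0,
    perturbation=None, convention: str = "count",
) -> PredictionReport:
    """Normalized Euclidean norm of the prediction residual.

    ``kind='vector'`` divides the norm by the number of entries,
    ``kind='matrix'`` by its square; ``convention='sqrt'`` divides by the
    square root of those counts instead.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: actual {actual.shape} vs predicted {predicted.shape}"
        )
    raw = float(np.linalg.norm(actual - predicted))
    count = actual.size
    if kind == "vector":
        normalization = float(count)
    elif kind == "matrix":
        normalization = float(count) ** 2
    else:
        raise ValueError("kind must be 'vector' or 'matrix'")
    if convention == "sqrt":
        normalization = np.sqrt(normalization)
    elif convention != "count":
        raise ValueError("convention must be 'count' or 'sqrt'")
    v = np.zeros(0) if perturbation is None else np.asarray(perturbation, dtype=float)
    return PredictionReport(order, v, raw / normalization, raw, normalization)


def perturb_params(p, magnitude: float, rng_seed: int):
    """Randomly perturb each parameter by a relative factor.

    Each p_i becomes p_i(1 + U_i) with U_i ~ Uniform(−magnitude,
    magnitude) drawn from a generator seeded with ``rng_seed``.  Returns
    the perturbed vector and the displacement v = p∘U.
    """
    if not 0.0 < magnitude < 1.0:
        raise ValueError("magnitude must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform(-magnitude, magnitude, size=p.shape)
    v = p * u
    return p + v, v
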