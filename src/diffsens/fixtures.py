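"""Fixture generators and analytic test functions.

Random birth-death-migration processes are drawn on the rate ranges used
throughout the package's benchmarks (β ∈ [0.05, 0.16], δ ∈ [0.05, 0.19],
λ ∈ [0.0003, 0.00046]); a criticality mode replaces δ by β ± 0.03 to
force a sub- or supercritical regime.  The test-function registry holds
small closed-form maps with known Jacobians and Hessians for validating
the derivative engines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .branching import BDMProcess
from .derivatives import TargetFunction

__all__ = ["BDMFixtureSpec", "random_bdm", "TEST_FUNCTIONS", "get_test_function"]

#: criticality offset applied to δ relative to β
_CRITICALITY_OFFSET = 0.03


@dataclass(frozen=True)
class BDMFixtureSpec:
    """Sampling ranges and criticality mode for random processes."""

    n_types: int = 2
    beta_range: tuple = (0.05, 0.16)
    delta_range: tuple = (0.05, 0.19)
    lambda_range: tuple = (0.0003, 0.00046)
    criticality: str = "free"
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 1:
            raise ValueError("n_types must be positive")
        for lo, hi in (self.beta_range, self.delta_range, self.lambda_range):
            if not (0 <= lo <= hi):
                raise ValueError("ranges must be ordered and nonnegative")
        if self.criticality not in ("free", "subcritical", "supercritical"):
            raise ValueError("criticality must be free, subcritical or supercritical")


def random_bdm(spec: BDMFixtureSpec) -> BDMProcess:
    """Draw a random process uniformly on the spec's rate ranges.

    ``criticality='subcritical'`` overrides δ = β + 0.03 (so every node
    dies faster than it births and ρ < 0 for small migration rates);
    ``'supercritical'`` sets δ = β − 0.03 and raises if that would make
    any death rate nonpositive.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_types
    beta = rng.uniform(*spec.beta_range, size=n)
    if spec.criticality == "free":
        delta = rng.uniform(*spec.delta_range, size=n)
    elif spec.criticality == "subcritical":
        delta = beta + _CRITICALITY_OFFSET
    else:
        delta = beta - _CRITICALITY_OFFSET
        if np.any(delta <= 0):
            raise ValueError(
                "supercritical offset would produce a nonpositive death rate; "
                "raise the lower end of beta_range above "
                f"{_CRITICALITY_OFFSET}"
            )
    lam = rng.uniform(*spec.lambda_range, size=(n, n))
    np.fill_diagonal(lam, 0.0)
    return BDMProcess(beta=beta, delta=delta, lam=lam)


def _square(p):
    return np.array([p[0] ** 2])


def _polyprod(p):
    return np.array([p[0] + p[1] * p[2]])


def _exp_sin(p):
    return np.array([np.sin(p[0]) * np.exp(p[1])])


def _decay(p):
    # I0 e^{-delta t} observed at t = 10 with I0 = 100
    return np.array([100.0 * np.exp(-p[0] * 10.0)])


def _quadratic3(p):
    return np.array(
        [
            p[0] ** 2 + 2.0 * p[0] * p[1] + 3.0 * p[2] ** 2,
            p[1] * p[2] + p[0],
        ]
    )


TEST_FUNCTIONS = {
    "square": TargetFunction(_square, 1, 1, name="square"),
    "polyprod": TargetFunction(_polyprod, 3, 1, name="polyprod"),
    "exp_sin": TargetFunction(_exp_sin, 2, 1, name="exp_sin"),
    "decay": TargetFunction(_decay, 1, 1, name="decay"),
    "quadratic3": TargetFunction(_quadratic3, 3, 2, name="quadratic3"),
}


def get_test_function(name: str) -> TargetFunction:
    try:
        return TEST_FUNCTIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown test function {name!r}; available: "
            f"{', '.join(sorted(TEST_FUNCTIONS))}"
        ) from None
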