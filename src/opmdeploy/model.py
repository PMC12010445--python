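"""Logistic generative model for a binary covariate, treatment and outcome.

The data-generating process is

    X ~ Bernoulli(p_x)
    T = policy(X)                       (deterministic treatment assignment)
    Y ~ Bernoulli(sigma(eta)),  eta = beta0 + beta_x*X + beta_t*T + beta_xt*X*T

where ``sigma`` is the standard logistic function.  Everything in this
module is closed form: potential-outcome probabilities, the joint
distribution of (X, Y) induced by any deterministic policy, and
treatment effects per covariate group.  No sampling happens here; finite
cohorts live in :mod:`opmdeploy.cohort`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import InvalidParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .policy import Policy

__all__ = [
    "OutcomeModelParams",
    "PotentialOutcomeTable",
    "JointDistribution",
    "sigmoid",
    "potential_outcomes",
    "outcome_distribution",
    "treatment_effect",
    "marginal_treatment_effect",
]

_MASS_TOL = 1e-12


def sigmoid(eta: float) -> float:
    """Numerically stable logistic function sigma(eta) = 1/(1+exp(-eta))."""
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    z = math.exp(eta)
    return z / (1.0 + z)


@dataclass(frozen=True)
class OutcomeModelParams:
    """Parameters of the logistic outcome model.

    Attributes
    ----------
    beta0 : float
        Log-odds intercept.
    beta_x : float
        Log-odds effect of the covariate X.
    beta_t : float
        Log-odds main effect of treatment T.
    beta_xt : float
        Log-odds treatment-covariate interaction.
    p_x : float
        Prevalence of X = 1, strictly inside (0, 1).
    """

    beta0: float
    beta_x: float
    beta_t: float
    beta_xt: float
    p_x: float

    def __post_init__(self) -> None:
        for name in ("beta0", "beta_x", "beta_t", "beta_xt"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be a finite real, got {v!r}")
        if not (isinstance(self.p_x, (int, float)) and math.isfinite(self.p_x)):
            raise InvalidParameterError(f"p_x must be a finite real, got {self.p_x!r}")
        if not 0.0 < self.p_x < 1.0:
            raise InvalidParameterError(f"p_x must lie strictly in (0, 1), got {self.p_x}")

    def linear_predictor(self, x: int, t: int) -> float:
        """Log-odds eta for covariate value ``x`` under treatment ``t``."""
        return self.beta0 + self.beta_x * x + self.beta_t * t + self.beta_xt * x * t

    def outcome_probability(self, x: int, t: int) -> float:
        """p(Y^t = 1 | X = x) = sigma(eta(x, t))."""
        return sigmoid(self.linear_predictor(x, t))


@dataclass(frozen=True)
class PotentialOutcomeTable:
    """The four potential-outcome probabilities p(Y^t = 1 | X = x).

    ``prob[t][x]`` indexes by treatment first, covariate second.  All
    entries are strictly inside (0, 1) — guaranteed for finite logistic
    parameters and asserted on construction, which is exactly the
    non-degeneracy condition the closed-form AUC relies on.
    """

    prob: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        for t in (0, 1):
            for x in (0, 1):
                p = self.prob[t][x]
                if not 0.0 < p < 1.0:
                    raise InvalidParameterError(
                        f"p(Y^{t}=1|X={x}) = {p} is not strictly inside (0, 1)"
                    )

    def __getitem__(self, t: int) -> tuple[float, float]:
        return self.prob[t]

    def treatment_effect(self, x: int) -> float:
        """p(Y^1 = 1 | X = x) - p(Y^0 = 1 | X = x), in (-1, 1)."""
        return self.prob[1][x] - self.prob[0][x]


@dataclass(frozen=True)
class JointDistribution:
    """Joint distribution of (X, Y) induced by a deterministic policy.

    ``mass[x][y]`` is p(X = x, Y = y).  The X-marginal is policy
    invariant: it always equals (1 - p_x, p_x).
    """

    mass: tuple[tuple[float, float], tuple[float, float]]
    policy_label: str = ""

    def __post_init__(self) -> None:
        total = sum(self.mass[x][y] for x in (0, 1) for y in (0, 1))
        if abs(total - 1.0) > _MASS_TOL:
            raise InvalidParameterError(f"joint masses sum to {total}, not 1")
        if any(self.mass[x][y] < 0 for x in (0, 1) for y in (0, 1)):
            raise InvalidParameterError("joint masses must be non-negative")

    def p_x(self, x: int) -> float:
        """Marginal p(X = x)."""
        return self.mass[x][0] + self.mass[x][1]

    def p_y(self, y: int) -> float:
        """Marginal p(Y = y)."""
        return self.mass[0][y] + self.mass[1][y]

    def p_y_given_x(self, y: int, x: int) -> float:
        """Conditional p(Y = y | X = x)."""
        return self.mass[x][y] / self.p_x(x)

    def p_x_given_y(self, x: int, y: int) -> float:
        """Conditional p(X = x | Y = y)."""
        return self.mass[x][y] / self.p_y(y)


def potential_outcomes(params: OutcomeModelParams) -> PotentialOutcomeTable:
    """Evaluate p(Y^t = 1 | X = x) = sigma(beta0 + beta_x*x + beta_t*t + beta_xt*x*t)."""
    return PotentialOutcomeTable(
        prob=tuple(
            tuple(params.outcome_probability(x, t) for x in (0, 1)) for t in (0, 1)
        )
    )


def outcome_distribution(params: OutcomeModelParams, policy: "Policy") -> JointDistribution:
    """Joint (X, Y) distribution when treatment is assigned by ``policy``.

    Under a deterministic policy pi, p_pi(Y=1|X=x) = p(Y^{pi(x)}=1|X=x),
    so the joint mass is p(X=x) * p(Y^{pi(x)}=y|X=x).
    """
    table = potential_outcomes(params)
    px = (1.0 - params.p_x, params.p_x)
    mass = []
    for x in (0, 1):
        p1 = table[policy(x)][x]
        mass.append((px[x] * (1.0 - p1), px[x] * p1))
    return JointDistribution(mass=tuple(mass), policy_label=policy.label)


def treatment_effect(params: OutcomeModelParams, x: int) -> float:
    """Group-x treatment effect p(Y^1=1|X=x) - p(Y^0=1|X=x)."""
    if x not in (0, 1):
        raise InvalidParameterError(f"x must be 0 or 1, got {x!r}")
    return potential_outcomes(params).treatment_effect(x)


def marginal_treatment_effect(params: OutcomeModelParams) -> float:
    """Prevalence-weighted average treatment effect across the two groups."""
    table = potential_outcomes(params)
    return (1.0 - params.p_x) * table.treatment_effect(0) + params.p_x * table.treatment_effect(1)
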