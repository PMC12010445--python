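"""Treatment policies and the historically fitted outcome prediction model.

A *policy* maps the binary covariate to a treatment decision.  The
*historical* policy is constant (everyone treated, or no one), and the
OPM is the infinite-data model fitted on records generated under it:
its score for group x is exactly p0(Y=1|X=x), so it is calibrated on
the historical distribution by construction.  The *informed* policy
treats a patient iff the score strictly exceeds a threshold lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AssumptionViolationError, DegenerateOPMError
from .model import OutcomeModelParams, potential_outcomes

__all__ = [
    "Policy",
    "OPM",
    "constant_policy",
    "fit_historical_opm",
    "default_threshold",
    "informed_policy",
]


@dataclass(frozen=True)
class Policy:
    """Deterministic treatment assignment x -> t for x in {0, 1}."""

    assignment: tuple[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        if any(t not in (0, 1) for t in self.assignment):
            raise AssumptionViolationError(
                f"treatment decisions must be 0 or 1, got {self.assignment!r}"
            )

    def __call__(self, x: int) -> int:
        return self.assignment[x]

    @property
    def is_constant(self) -> bool:
        return self.assignment[0] == self.assignment[1]


def constant_policy(t: int, label: str = "historical") -> Policy:
    """The constant policy assigning treatment ``t`` to everyone."""
    return Policy(assignment=(t, t), label=label)


@dataclass(frozen=True)
class OPM:
    """An outcome prediction model on the binary covariate: two scores and a threshold.

    ``score[x]`` is the predicted probability of Y = 1 for group x;
    ``threshold`` is the decision cutoff lambda.  A ``threshold`` of
    ``None`` means no cutoff has been chosen yet.
    """

    score: tuple[float, float]
    threshold: float | None = None
    label: str = field(default="opm")

    def __post_init__(self) -> None:
        if any(not 0.0 <= s <= 1.0 for s in self.score):
            raise DegenerateOPMError(f"scores must lie in [0, 1], got {self.score!r}")

    def __call__(self, x: int) -> float:
        return self.score[x]

    @property
    def is_constant(self) -> bool:
        """True when both groups receive the same score.

        A constant OPM induces a constant informed policy for every
        threshold, which violates the non-constant-policy assumption.
        """
        return self.score[0] == self.score[1]

    @property
    def higher_scored_group(self) -> int:
        if self.is_constant:
            raise DegenerateOPMError("scores are tied; no higher-scored group")
        return 1 if self.score[1] > self.score[0] else 0


def fit_historical_opm(
    params: OutcomeModelParams, historical_policy: Policy, with_threshold: bool = True
) -> OPM:
    """The infinite-data OPM trained under a constant historical policy.

    Its score for group x is the historical conditional outcome rate
    p0(Y=1|X=x) = p(Y^t0=1|X=x) with t0 the constant historical
    treatment — the best possible predictor of the historical data, and
    calibrated on it by construction.  The default threshold (midpoint
    of the two scores) is attached unless ``with_threshold`` is False.

    Raises
    ------
    AssumptionViolationError
        If the historical policy is not constant.
    """
    if not historical_policy.is_constant:
        raise AssumptionViolationError(
            "the historical policy must be constant and deterministic; "
            f"got assignment {historical_policy.assignment!r}"
        )
    t0 = historical_policy(0)
    table = potential_outcomes(params)
    scores = (table[t0][0], table[t0][1])
    opm = OPM(score=scores, label="historical-fit")
    if with_threshold and scores[0] != scores[1]:
        opm = OPM(score=scores, threshold=default_threshold(opm), label="historical-fit")
    return opm


def default_threshold(opm: OPM) -> float:
    """Midpoint of the two scores.

    Any threshold strictly between the two scores induces the same
    informed policy (treat exactly the higher-scored group), so the
    midpoint is a canonical, arbitrary-free choice.
    """
    if opm.is_constant:
        raise DegenerateOPMError(
            "both groups share one score; no threshold separates them"
        )
    return 0.5 * (opm.score[0] + opm.score[1])


def informed_policy(opm: OPM) -> Policy:
    """The policy informed by the OPM: treat iff score(x) > lambda.

    Ties at the threshold receive no treatment (strict inequality).

    Raises
    ------
    DegenerateOPMError
        If no threshold is attached.
    AssumptionViolationError
        If the resulting policy is constant — every result here assumes
        the new policy actually varies with X, so such configurations
        must be excluded, not silently processed.
    """
    if opm.threshold is None:
        raise DegenerateOPMError("OPM has no threshold attached")
    assignment = tuple(int(opm.score[x] > opm.threshold) for x in (0, 1))
    policy = Policy(assignment=assignment, label="informed")
    if policy.is_constant:
        raise AssumptionViolationError(
            f"informed policy is constant ({assignment[0]}) at threshold "
            f"{opm.threshold}; the framework requires a policy that varies with X"
        )
    return policy
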