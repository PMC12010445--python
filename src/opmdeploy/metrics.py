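"""Pre/post-deployment discrimination, harm and calibration, in closed form.

Deploying an OPM-informed policy changes the outcome distribution, so
the model's AUC, its calibration, and — crucially — patient outcomes
all differ between the historical and the deployment regime.  With a
binary covariate everything is available in closed form:

* the AUC of a two-level score is ``1/2 + [P(X=x_hi|Y=1) - P(X=x_hi|Y=0)]/2``
  where ``x_hi`` is the higher-scored group (ties get half credit);
* a deployment is *self-fulfilling* when the AUC does not decrease;
* it is *harmful to group x* when that group's expected outcome gets
  strictly worse than under the historical policy, where "worse" is
  read through the outcome polarity;
* the OPM stays calibrated post-deployment iff, for every group, the
  policy did not change or the treatment effect there is zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
from scipy.stats import rankdata

from .errors import AssumptionViolationError, UndefinedAUCError
from .model import (
    JointDistribution,
    OutcomeModelParams,
    marginal_treatment_effect,
    outcome_distribution,
    potential_outcomes,
)
from .policy import OPM, Policy, fit_historical_opm, informed_policy
from .scenario import Polarity, ScenarioConfig

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import SampleSet

__all__ = [
    "HarmVerdict",
    "DeploymentReport",
    "auc_closed_form",
    "auc_empirical",
    "assess_harm",
    "calibration_check",
    "verify_theorem10",
    "evaluate_scenario",
]

#: slack for the AUC(post) >= AUC(pre) boundary: equality counts as
#: self-fulfilling, and exact closed-form equality deserves protection
#: from the last floating-point bit.
SELF_FULFILLING_SLACK = 1e-12

#: absolute tolerance deciding whether a closed-form probability change
#: is exactly zero (neutral) rather than harmful/beneficial.
ZERO_EFFECT_TOL = 1e-9


class HarmVerdict(str, enum.Enum):
    HARMFUL = "harmful"
    BENEFICIAL = "beneficial"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class DeploymentReport:
    """Everything a deployment evaluation produces, pre vs post.

    ``harm_by_group`` maps each covariate value to its verdict; under
    the constant-historical / non-constant-informed setup exactly one
    group changes treatment, so the other group is always neutral and
    the marginal verdict equals the changed group's verdict.
    """

    auc_pre: float
    auc_post: float
    delta_auc: float
    self_fulfilling: bool
    harm_by_group: Mapping[int, HarmVerdict]
    marginal_harm: HarmVerdict
    calibrated_pre: bool
    calibrated_post: bool
    polarity: Polarity

    def to_flat_dict(self) -> dict:
        """Flatten into plain scalars, e.g. for a CSV row."""
        return {
            "auc_pre": self.auc_pre,
            "auc_post": self.auc_post,
            "delta_auc": self.delta_auc,
            "self_fulfilling": self.self_fulfilling,
            "harm_group0": self.harm_by_group[0].value,
            "harm_group1": self.harm_by_group[1].value,
            "marginal_harm": self.marginal_harm.value,
            "calibrated_pre": self.calibrated_pre,
            "calibrated_post": self.calibrated_post,
            "polarity": self.polarity.value,
        }


def auc_closed_form(opm: OPM, dist: JointDistribution) -> float:
    """Population AUC of the OPM's score as a predictor of Y = 1.

    With a two-level score the ROC has a single interior vertex and

        AUC = 1/2 + [P(X=x_hi | Y=1) - P(X=x_hi | Y=0)] / 2,

    x_hi being the higher-scored group; tied scores give 1/2.  Values
    below 1/2 are legal: post-deployment the score can rank worse than
    chance.  Note the AUC never depends on outcome polarity.
    """
    if dist.p_y(1) <= 0.0 or dist.p_y(0) <= 0.0:
        raise UndefinedAUCError(
            "AUC is undefined: the outcome margin is degenerate "
            f"(p(Y=1) = {dist.p_y(1)})"
        )
    if opm.is_constant:
        return 0.5
    x_hi = opm.higher_scored_group
    a = dist.p_x_given_y(x_hi, 1)
    b = dist.p_x_given_y(x_hi, 0)
    return 0.5 + (a - b) / 2.0


def auc_empirical(opm: OPM, cohort: "SampleSet") -> float:
    """Mann-Whitney AUC of the OPM score on a finite cohort.

    Equals the fraction of case-control pairs the score orders
    correctly, counting ties as half — computed via midranks, which is
    algebraically identical to brute-force pair enumeration.
    """
    scores = np.asarray([opm(x) for x in cohort.x], dtype=float)
    y = np.asarray(cohort.y, dtype=bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError(
            f"cohort has {n1} cases and {n0} controls; AUC needs both classes"
        )
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _verdict(delta: float, polarity: Polarity, tol: float) -> HarmVerdict:
    """Classify a change in p(Y=1) given which direction is good."""
    if abs(delta) <= tol:
        return HarmVerdict.NEUTRAL
    good = delta > 0 if polarity is Polarity.DESIRABLE else delta < 0
    return HarmVerdict.BENEFICIAL if good else HarmVerdict.HARMFUL


def assess_harm(
    params: OutcomeModelParams,
    pi0: Policy,
    pif: Policy,
    polarity: Polarity,
    tol: float = ZERO_EFFECT_TOL,
) -> tuple[dict[int, HarmVerdict], HarmVerdict]:
    """Per-group and marginal harm of replacing ``pi0`` with ``pif``.

    Group x is harmed when its expected outcome strictly worsens:
    p_f(Y=1|X=x) < p_0(Y=1|X=x) when Y=1 is desirable, with the
    inequality reversed for an undesirable outcome.  Changes within
    ``tol`` of zero are neutral.  Returns ``(harm_by_group,
    marginal_harm)``.
    """
    if not pi0.is_constant:
        raise AssumptionViolationError("the historical policy must be constant")
    if pif.is_constant:
        raise AssumptionViolationError("the informed policy must not be constant")
    table = potential_outcomes(params)
    by_group: dict[int, HarmVerdict] = {}
    marginal_delta = 0.0
    weights = (1.0 - params.p_x, params.p_x)
    for x in (0, 1):
        delta = table[pif(x)][x] - table[pi0(x)][x]
        by_group[x] = _verdict(delta, polarity, tol)
        marginal_delta += weights[x] * delta
    return by_group, _verdict(marginal_delta, polarity, tol)


def calibration_check(
    opm: OPM, dist: JointDistribution, tol: float = ZERO_EFFECT_TOL
) -> bool:
    """Is the OPM calibrated with respect to ``dist``?

    Calibration requires E[Y | f(X) = alpha] = alpha at every attained
    score level.  With distinct scores each group is its own level, so
    the check is f(x) = p(Y=1|X=x) per group; with tied scores the two
    groups pool into one level and the pooled rate must match it.
    """
    if opm.is_constant:
        return abs(dist.p_y(1) - opm.score[0]) <= tol
    return all(abs(dist.p_y_given_x(1, x) - opm(x)) <= tol for x in (0, 1))


def verify_theorem10(
    params: OutcomeModelParams, pi0: Policy, tol: float = ZERO_EFFECT_TOL
) -> bool:
    """Check the calibration biconditional on one configuration.

    For an OPM calibrated on historical data with a non-constant
    informed policy, post-deployment calibration holds iff for every
    group the policy did not change or the treatment effect there is
    zero.  Returns True when the two sides agree (they should, always);
    a False return means the claimed equivalence failed numerically.
    """
    opm = fit_historical_opm(params, pi0)
    pif = informed_policy(opm)
    table = potential_outcomes(params)
    lhs = calibration_check(opm, outcome_distribution(params, pif), tol)
    rhs = all(
        pi0(x) == pif(x) or abs(table.treatment_effect(x)) <= tol for x in (0, 1)
    )
    return lhs == rhs


def evaluate_scenario(
    scenario: ScenarioConfig, tol: float = ZERO_EFFECT_TOL
) -> DeploymentReport:
    """Full closed-form deployment evaluation of one scenario.

    Fits the historical OPM, derives the informed policy, and compares
    the historical and deployment distributions on AUC, harm and
    calibration.

    Raises
    ------
    AssumptionViolationError
        If the informed policy would be constant (tied scores, or a
        threshold outside the score range).
    """
    params = scenario.params
    pi0 = scenario.pi0
    opm = fit_historical_opm(params, pi0)
    pif = informed_policy(opm)
    dist_pre = outcome_distribution(params, pi0)
    dist_post = outcome_distribution(params, pif)
    auc_pre = auc_closed_form(opm, dist_pre)
    auc_post = auc_closed_form(opm, dist_post)
    delta = auc_post - auc_pre
    harm_by_group, marginal = assess_harm(params, pi0, pif, scenario.polarity, tol)
    return DeploymentReport(
        auc_pre=auc_pre,
        auc_post=auc_post,
        delta_auc=delta,
        self_fulfilling=delta >= -SELF_FULFILLING_SLACK,
        harm_by_group=harm_by_group,
        marginal_harm=marginal,
        calibrated_pre=calibration_check(opm, dist_pre, tol),
        calibrated_post=calibration_check(opm, dist_post, tol),
        polarity=scenario.polarity,
    )
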