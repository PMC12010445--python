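"""Post-hoc deployment audit from observable information only.

After an OPM has been deployed for treatment decisions, three facts are
typically observable without any access to counterfactual outcomes:
whether Y = 1 is desirable, whether the historical policy treated
everyone or no one, and whether the model's AUC rose or fell after
deployment.  Under the framework's assumptions (constant historical
policy, non-constant informed policy, stable covariate marginal) these
three already determine whether the deployment harmed patients.

The logic, with a strictly positive AUC change ("self-fulfilling"):

=============  ================  ==========  ===========
Y=1 is         historical rule   AUC change  deployment
=============  ================  ==========  ===========
desirable      treat everyone    rose        harmful
desirable      treat everyone    fell        beneficial
desirable      treat no one      rose        beneficial
desirable      treat no one      fell        harmful
undesirable    treat everyone    rose        beneficial
undesirable    treat everyone    fell        harmful
undesirable    treat no one      rose        harmful
undesirable    treat no one      fell        beneficial
=============  ================  ==========  ===========

An exactly-zero change is not covered by the strict signs above and is
reported as indeterminate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import InvalidParameterError
from .scenario import Polarity

__all__ = ["DeltaSign", "AuditOutcome", "AuditVerdict", "table1_audit", "delta_sign"]


class DeltaSign(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    ZERO = "zero"


class AuditOutcome(str, enum.Enum):
    HARMFUL = "harmful"
    BENEFICIAL = "beneficial"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class AuditVerdict:
    polarity: Polarity
    historical_policy: int
    delta_auc_sign: DeltaSign
    verdict: AuditOutcome

    def describe(self) -> str:
        pol = "desirable" if self.polarity is Polarity.DESIRABLE else "undesirable"
        rule = "treat everyone" if self.historical_policy == 1 else "treat no one"
        change = {
            DeltaSign.POSITIVE: "AUC rose (self-fulfilling)",
            DeltaSign.NEGATIVE: "AUC fell (not self-fulfilling)",
            DeltaSign.ZERO: "AUC unchanged",
        }[self.delta_auc_sign]
        return (
            f"Y=1 {pol}, historical policy '{rule}', {change} "
            f"=> deployment was {self.verdict.value}"
        )


def delta_sign(delta_auc: float, tol: float = 0.0) -> DeltaSign:
    """Sign of an AUC change, with |delta| <= tol treated as zero."""
    if delta_auc > tol:
        return DeltaSign.POSITIVE
    if delta_auc < -tol:
        return DeltaSign.NEGATIVE
    return DeltaSign.ZERO


def table1_audit(
    polarity: Polarity, historical_policy: int, delta_auc_sign: DeltaSign
) -> AuditVerdict:
    """Infer harm/benefit from polarity, historical rule and AUC change.

    Intuition for the first row: with everyone historically treated and
    a desirable outcome, the informed policy withdraws treatment from
    the low-scored group; the AUC can only rise if that group's
    outcomes got *worse*, so a rising AUC certifies harm.  Every other
    row follows by flipping the historical rule (which group changes)
    or the polarity (which direction is bad).
    """
    if historical_policy not in (0, 1):
        raise InvalidParameterError(
            f"historical_policy must be 0 or 1, got {historical_policy!r}"
        )
    polarity = Polarity(polarity)
    delta_auc_sign = DeltaSign(delta_auc_sign)
    if delta_auc_sign is DeltaSign.ZERO:
        verdict = AuditOutcome.INDETERMINATE
    else:
        rose = delta_auc_sign is DeltaSign.POSITIVE
        treated_historically = historical_policy == 1
        desirable = polarity is Polarity.DESIRABLE
        # three binary flips around the anchor row (desirable, treat
        # everyone, AUC rose) => harmful
        harmful = rose == (treated_historically == desirable)
        verdict = AuditOutcome.HARMFUL if harmful else AuditOutcome.BENEFICIAL
    return AuditVerdict(
        polarity=polarity,
        historical_policy=historical_policy,
        delta_auc_sign=delta_auc_sign,
        verdict=verdict,
    )
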