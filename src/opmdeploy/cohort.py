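"""Finite-cohort sampling from the generative process, and the empirical
mirror of the closed-form deployment report.

The sampler draws X ~ Bernoulli(p_x), assigns T = policy(X), and draws
Y ~ Bernoulli(sigma(eta)) — the exact finite-sample counterpart of the
closed-form distributions, and the Monte Carlo oracle for every
closed-form quantity in the package.  All randomness is explicit: a
seed is required, never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .errors import InvalidParameterError
from .metrics import DeploymentReport, HarmVerdict, auc_empirical
from .model import OutcomeModelParams, potential_outcomes
from .policy import OPM, Policy
from .scenario import Polarity, ScenarioConfig

__all__ = ["SampleSet", "sample_cohort", "empirical_report", "EmpiricalDeploymentReport"]

#: minimum per-group cell size below which finite-sample verdicts are
#: flagged as low confidence
LOW_CONFIDENCE_GROUP_SIZE = 30


@dataclass(frozen=True)
class SampleSet:
    """A finite cohort of (x, t, y) records with its generating context."""

    x: np.ndarray
    t: np.ndarray
    y: np.ndarray
    seed: int
    provenance: ScenarioConfig | None = None

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.t) == len(self.y)):
            raise InvalidParameterError("x, t, y must have equal length")

    @property
    def n(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "t": self.t, "y": self.y})

    def save(self, path: str | Path) -> None:
        """Write records as CSV with header x,t,y; provenance as a YAML sidecar."""
        self.to_frame().to_csv(path, index=False)
        if self.provenance is not None:
            self.provenance.save(Path(path).with_suffix(".scenario.yaml"))

    @classmethod
    def load(cls, path: str | Path, seed: int = -1) -> "SampleSet":
        frame = pd.read_csv(path)
        sidecar = Path(path).with_suffix(".scenario.yaml")
        prov = ScenarioConfig.load(sidecar) if sidecar.exists() else None
        return cls(
            x=frame["x"].to_numpy(np.int8),
            t=frame["t"].to_numpy(np.int8),
            y=frame["y"].to_numpy(np.int8),
            seed=seed,
            provenance=prov,
        )


def sample_cohort(
    params: OutcomeModelParams,
    policy: Policy,
    n: int,
    seed: int,
    polarity: Polarity = Polarity.DESIRABLE,
) -> SampleSet:
    """Draw ``n`` patients under a deterministic treatment policy.

    x ~ Bernoulli(p_x); t = policy(x); y ~ Bernoulli(sigma(eta(x, t))).
    Identical inputs give identical records.
    """
    if n < 1:
        raise InvalidParameterError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    table = potential_outcomes(params)
    x = (rng.random(n) < params.p_x).astype(np.int8)
    t = np.where(x == 1, policy(1), policy(0)).astype(np.int8)
    p1 = np.where(
        x == 1,
        np.where(t == 1, table[1][1], table[0][1]),
        np.where(t == 1, table[1][0], table[0][0]),
    )
    y = (rng.random(n) < p1).astype(np.int8)
    t0 = policy(0) if policy.is_constant else None
    prov = (
        ScenarioConfig(params=params, historical_policy=t0, polarity=polarity)
        if t0 is not None
        else None
    )
    return SampleSet(x=x, t=t, y=y, seed=seed, provenance=prov)


def _empirically_calibrated(cohort: SampleSet, opm: OPM, tol: float) -> bool:
    """Compare observed outcome rates per score level to the scores.

    With distinct scores each covariate group is its own level; with
    tied scores the pooled rate is compared to the common score.  Groups
    absent from the cohort attain no score level and are skipped.
    """
    if opm.is_constant:
        return abs(_rate(cohort.y) - opm.score[0]) <= tol
    for x in (0, 1):
        y = cohort.y[cohort.x == x]
        if len(y) and abs(_rate(y) - opm(x)) > tol:
            return False
    return True


@dataclass(frozen=True)
class EmpiricalDeploymentReport:
    """Finite-sample deployment report, structured like the closed form.

    Harm verdicts come from two-proportion z-tests on the per-group
    outcome rates at significance level ``alpha`` — a reporting
    heuristic; the distributional definitions remain the ground truth.
    ``low_confidence`` is set when any (cohort, group) cell is small.
    """

    report: DeploymentReport
    n_pre: int
    n_post: int
    p_values_by_group: dict[int, float]
    alpha: float
    low_confidence: bool


def _rate(y: np.ndarray) -> float:
    return float(np.mean(y)) if len(y) else float("nan")


def empirical_report(
    cohort_pre: SampleSet,
    cohort_post: SampleSet,
    opm: OPM,
    polarity: Polarity,
    alpha: float = 0.05,
    calibration_tol: float = 0.02,
) -> EmpiricalDeploymentReport:
    """Estimate the deployment report from two finite cohorts.

    ``cohort_pre`` must be sampled under the historical policy and
    ``cohort_post`` under the informed policy, from the same generative
    parameters.  AUCs are Mann-Whitney statistics; per-group harm uses a
    two-proportion z-test (below ``alpha`` and in the bad direction =>
    harmful); calibration compares group rates to scores within
    ``calibration_tol``.
    """
    auc_pre = auc_empirical(opm, cohort_pre)
    auc_post = auc_empirical(opm, cohort_post)
    delta = auc_post - auc_pre

    harm: dict[int, HarmVerdict] = {}
    pvals: dict[int, float] = {}
    low_confidence = False
    deltas_weighted = 0.0
    signif = []
    for x in (0, 1):
        pre_y = cohort_pre.y[cohort_pre.x == x]
        post_y = cohort_post.y[cohort_post.x == x]
        if min(len(pre_y), len(post_y)) < LOW_CONFIDENCE_GROUP_SIZE:
            low_confidence = True
        d = _rate(post_y) - _rate(pre_y)
        counts = np.array([post_y.sum(), pre_y.sum()])
        nobs = np.array([len(post_y), len(pre_y)])
        if counts.sum() in (0, nobs.sum()) or 0 in nobs:
            pval = 1.0  # no variation: cannot distinguish the rates
        else:
            _, pval = proportions_ztest(counts, nobs)
        pvals[x] = float(pval)
        if pval < alpha and d != 0.0:
            good = d > 0 if polarity is Polarity.DESIRABLE else d < 0
            harm[x] = HarmVerdict.BENEFICIAL if good else HarmVerdict.HARMFUL
            signif.append((x, d))
        else:
            harm[x] = HarmVerdict.NEUTRAL
        weight = float(np.mean(np.concatenate([cohort_pre.x, cohort_post.x]) == x))
        deltas_weighted += weight * (d if np.isfinite(d) else 0.0)

    if signif:
        good = deltas_weighted > 0 if polarity is Polarity.DESIRABLE else deltas_weighted < 0
        marginal = HarmVerdict.BENEFICIAL if good else HarmVerdict.HARMFUL
    else:
        marginal = HarmVerdict.NEUTRAL

    report = DeploymentReport(
        auc_pre=auc_pre,
        auc_post=auc_post,
        delta_auc=delta,
        self_fulfilling=delta >= 0.0,
        harm_by_group=harm,
        marginal_harm=marginal,
        calibrated_pre=_empirically_calibrated(cohort_pre, opm, calibration_tol),
        calibrated_post=_empirically_calibrated(cohort_post, opm, calibration_tol),
        polarity=polarity,
    )
    return EmpiricalDeploymentReport(
        report=report,
        n_pre=cohort_pre.n,
        n_post=cohort_post.n,
        p_values_by_group=pvals,
        alpha=alpha,
        low_confidence=low_confidence,
    )
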