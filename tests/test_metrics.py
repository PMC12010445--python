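"""Closed-form deployment metrics: AUC, harm, calibration, and the
calibration biconditional — each checked against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from opmdeploy import (
    OPM,
    AssumptionViolationError,
    HarmVerdict,
    OutcomeModelParams,
    Polarity,
    Policy,
    SampleSet,
    UndefinedAUCError,
    assess_harm,
    auc_closed_form,
    auc_empirical,
    calibration_check,
    constant_policy,
    evaluate_scenario,
    fit_historical_opm,
    informed_policy,
    outcome_distribution,
    sample_cohort,
    verify_theorem10,
)

SIG1 = 1 / (1 + math.exp(-1))
SIG2 = 1 / (1 + math.exp(-2))

# frozen from an independent Bayes-rule hand computation:
# a = P(X=1|Y=1) = 0.546449..., b = P(X=1|Y=0) = 0.307110... pre-deployment
AUC_PRE = 0.619670
AUC_POST = 0.722690
DELTA_AUC = 0.103020


def brute_force_auc(scores, y):
    """Oracle: enumerate every case-control pair, half credit for ties."""
    cases = [s for s, yy in zip(scores, y) if yy == 1]
    controls = [s for s, yy in zip(scores, y) if yy == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestClosedFormAUC:
    def test_worked_example_pre_and_post(self, worked_params):
        pi0 = constant_policy(1)
        opm = fit_historical_opm(worked_params, pi0)
        pif = informed_policy(opm)
        pre = auc_closed_form(opm, outcome_distribution(worked_params, pi0))
        post = auc_closed_form(opm, outcome_distribution(worked_params, pif))
        assert pre == pytest.approx(AUC_PRE, abs=1e-5)
        assert post == pytest.approx(AUC_POST, abs=1e-5)
        assert post - pre == pytest.approx(DELTA_AUC, abs=1e-5)

    def test_tied_scores_give_half(self, worked_params):
        opm = OPM(score=(0.6, 0.6))
        dist = outcome_distribution(worked_params, constant_policy(1))
        assert auc_closed_form(opm, dist) == 0.5

    def test_no_separation_gives_half(self):
        """When X carries no outcome information, P(X|Y=1) = P(X|Y=0)."""
        params = OutcomeModelParams(beta0=0.4, beta_x=0, beta_t=0, beta_xt=0, p_x=0.3)
        opm = OPM(score=(0.2, 0.8))
        dist = outcome_distribution(params, constant_policy(0))
        assert auc_closed_form(opm, dist) == pytest.approx(0.5, abs=1e-12)

    def test_auc_can_fall_below_half(self):
        """Post-deployment the score may rank worse than chance."""
        # score prefers group 1 but group 1 has the worse outcome rate
        params = OutcomeModelParams(beta0=0, beta_x=-2, beta_t=0, beta_xt=0, p_x=0.5)
        opm = OPM(score=(0.2, 0.8))
        dist = outcome_distribution(params, constant_policy(0))
        assert auc_closed_form(opm, dist) < 0.5

    def test_monte_carlo_cross_check(self, worked_params):
        pi0 = constant_policy(1)
        opm = fit_historical_opm(worked_params, pi0)
        dist = outcome_distribution(worked_params, pi0)
        cohort = sample_cohort(worked_params, pi0, n=10**5, seed=20240101)
        closed = auc_closed_form(opm, dist)
        emp = auc_empirical(opm, cohort)
        assert abs(closed - emp) < 0.01


class TestEmpiricalAUC:
    def test_hand_enumerated_pairs(self):
        """Cases at x=(1,1,0), controls at x=(0,1): 6 pairs scoring
        (1 + 1 + 0.5 + 0.5 + 0 + 0.5)/6."""
        cohort = SampleSet(
            x=np.array([1, 1, 0, 0, 1]), t=np.zeros(5, dtype=int),
            y=np.array([1, 1, 1, 0, 0]), seed=0,
        )
        opm = OPM(score=(0.2, 0.8))
        assert auc_empirical(opm, cohort) == pytest.approx(3.5 / 6, abs=1e-12)

    def test_perfect_separation(self):
        cohort = SampleSet(
            x=np.array([1, 1, 0, 0]), t=np.zeros(4, dtype=int),
            y=np.array([1, 1, 0, 0]), seed=0,
        )
        assert auc_empirical(OPM(score=(0.1, 0.9)), cohort) == 1.0

    def test_all_ties_give_half(self):
        cohort = SampleSet(
            x=np.ones(6, dtype=int), t=np.zeros(6, dtype=int),
            y=np.array([1, 0, 1, 0, 1, 0]), seed=0,
        )
        assert auc_empirical(OPM(score=(0.1, 0.9)), cohort) == 0.5

    def test_single_class_cohort_rejected(self):
        cohort = SampleSet(
            x=np.array([0, 1]), t=np.zeros(2, dtype=int),
            y=np.array([1, 1]), seed=0,
        )
        with pytest.raises(UndefinedAUCError):
            auc_empirical(OPM(score=(0.1, 0.9)), cohort)

    @given(
        x=st.lists(st.integers(0, 1), min_size=4, max_size=40),
        data=st.data(),
    )
    def test_matches_brute_force_pair_enumeration(self, x, data):
        """The midrank Mann-Whitney statistic equals the fraction of
        correctly ordered case-control pairs on arbitrary cohorts."""
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=len(x), max_size=len(x))
        )
        if len(set(y)) < 2:
            y = ([0, 1] + y)[: len(x)] if len(x) >= 2 else y
        if len(set(y)) < 2:
            return
        cohort = SampleSet(
            x=np.array(x), t=np.zeros(len(x), dtype=int), y=np.array(y), seed=0
        )
        opm = OPM(score=(0.3, 0.7))
        scores = [opm(v) for v in x]
        assert auc_empirical(opm, cohort) == pytest.approx(
            brute_force_auc(scores, y), abs=1e-12
        )


class TestAssessHarm:
    def test_withdrawing_effective_treatment_harms_group0(self, worked_params):
        by_group, marginal = assess_harm(
            worked_params, constant_policy(1), Policy(assignment=(0, 1)),
            Polarity.DESIRABLE,
        )
        assert by_group[0] is HarmVerdict.HARMFUL  # 0.7311 -> 0.5
        assert by_group[1] is HarmVerdict.NEUTRAL
        assert marginal is HarmVerdict.HARMFUL  # 0.8059 -> 0.6904 on average

    def test_polarity_reversal_flips_the_verdict(self, worked_params):
        by_group, marginal = assess_harm(
            worked_params, constant_policy(1), Policy(assignment=(0, 1)),
            Polarity.UNDESIRABLE,
        )
        assert by_group[0] is HarmVerdict.BENEFICIAL
        assert marginal is HarmVerdict.BENEFICIAL

    def test_zero_effect_change_is_neutral(self):
        params = OutcomeModelParams(beta0=0.2, beta_x=1, beta_t=0, beta_xt=0, p_x=0.5)
        by_group, marginal = assess_harm(
            params, constant_policy(1), Policy(assignment=(0, 1)), Polarity.DESIRABLE
        )
        assert by_group == {0: HarmVerdict.NEUTRAL, 1: HarmVerdict.NEUTRAL}
        assert marginal is HarmVerdict.NEUTRAL

    def test_constant_informed_policy_rejected(self, worked_params):
        with pytest.raises(AssumptionViolationError):
            assess_harm(
                worked_params, constant_policy(1), constant_policy(0),
                Polarity.DESIRABLE,
            )


class TestCalibration:
    def test_calibrated_on_historical_but_not_deployment(self, worked_params):
        """Deployment withdraws treatment from group 0, dropping its
        outcome rate from sigma(1) to sigma(0) while the score still
        says sigma(1): calibration breaks exactly there."""
        pi0 = constant_policy(1)
        opm = fit_historical_opm(worked_params, pi0)
        pif = informed_policy(opm)
        assert calibration_check(opm, outcome_distribution(worked_params, pi0))
        assert not calibration_check(opm, outcome_distribution(worked_params, pif))

    def test_zero_treatment_effect_preserves_calibration(self):
        params = OutcomeModelParams(beta0=0, beta_x=1, beta_t=0, beta_xt=0, p_x=0.5)
        pi0 = constant_policy(1)
        opm = fit_historical_opm(params, pi0)
        pif = informed_policy(opm)
        assert calibration_check(opm, outcome_distribution(params, pif))

    def test_tied_scores_pool_to_the_common_level(self):
        params = OutcomeModelParams(beta0=0, beta_x=0, beta_t=0, beta_xt=0, p_x=0.5)
        dist = outcome_distribution(params, constant_policy(0))
        assert calibration_check(OPM(score=(0.5, 0.5)), dist)
        assert not calibration_check(OPM(score=(0.4, 0.4)), dist)


class TestTheorem10:
    def test_zero_effect_everywhere(self):
        params = OutcomeModelParams(beta0=0, beta_x=1, beta_t=0, beta_xt=0, p_x=0.5)
        assert verify_theorem10(params, constant_policy(1))

    def test_policy_change_with_nonzero_effect(self, worked_params):
        """Both sides of the biconditional are false here: the policy
        changes for group 0 where the effect is ~0.2311."""
        pi0 = constant_policy(1)
        assert verify_theorem10(worked_params, pi0)
        opm = fit_historical_opm(worked_params, pi0)
        pif = informed_policy(opm)
        assert not calibration_check(
            opm, outcome_distribution(worked_params, pif)
        )

    def test_change_only_where_effect_is_zero(self):
        """beta_t=0 with a positive interaction: the de-treated group
        (x=0) has exactly zero effect, so calibration survives
        deployment and both sides of the biconditional are true."""
        params = OutcomeModelParams(beta0=-0.5, beta_x=0.5, beta_t=0, beta_xt=1, p_x=0.4)
        pi0 = constant_policy(1)
        opm = fit_historical_opm(params, pi0)
        pif = informed_policy(opm)
        assert pif.assignment == (0, 1)  # group 0 loses treatment
        assert calibration_check(opm, outcome_distribution(params, pif))
        assert verify_theorem10(params, pi0)


def test_report_self_consistency(worked_scenario):
    rep = evaluate_scenario(worked_scenario)
    assert rep.delta_auc == pytest.approx(rep.auc_post - rep.auc_pre, abs=1e-15)
    assert rep.self_fulfilling == (rep.delta_auc >= -1e-12)
    flat = rep.to_flat_dict()
    assert flat["marginal_harm"] == "harmful"
    assert flat["polarity"] == "desirable"
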