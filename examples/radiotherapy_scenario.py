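"""A harmful self-fulfilling deployment, end to end.

The setting: palliative radiotherapy for end-stage cancer.  To reduce
overtreatment, a centre decides to keep treating only the patients with
the best expected 6-month survival.  A survival model is fitted on
historical records — where *everyone* was treated — using one binary
feature, tumour growth rate (X=1: slow-growing, better prognosis).
The catch: fast-growing tumours respond better to radiotherapy, so the
model-guided policy withdraws treatment from exactly the patients who
benefit most.

The numbers below show the trap: deployment harms the fast-growing
group, yet the model's AUC *rises*, making the deployment look like a
success to anyone monitoring discrimination.
"""

from opmdeploy import (
    OutcomeModelParams,
    Polarity,
    ScenarioConfig,
    evaluate_scenario,
    fit_historical_opm,
    informed_policy,
    marginal_treatment_effect,
    treatment_effect,
)

# Y=1 is 6-month survival (desirable).  Slow tumours (x=1) survive more
# (beta_x > 0); radiotherapy helps everyone (positive effect in both
# groups) but helps fast-growing tumours more (beta_xt < 0).
params = OutcomeModelParams(beta0=-0.5, beta_x=1.5, beta_t=1.5, beta_xt=-1.0, p_x=0.5)
scenario = ScenarioConfig(params=params, historical_policy=1,
                          polarity=Polarity.DESIRABLE)

print("Treatment effect (risk difference) per group:")
print(f"  fast-growing (x=0): {treatment_effect(params, 0):+.3f}")
print(f"  slow-growing (x=1): {treatment_effect(params, 1):+.3f}")
print(f"  average:            {marginal_treatment_effect(params):+.3f}")

opm = fit_historical_opm(params, scenario.pi0)
print(f"\nOPM fitted on historical (everyone-treated) data:")
print(f"  predicted survival: fast {opm(0):.3f}, slow {opm(1):.3f}")
print(f"  threshold lambda = {opm.threshold:.3f} "
      f"-> treat groups with assignment {informed_policy(opm).assignment} (x=0, x=1)")

rep = evaluate_scenario(scenario)
print(f"\nDeployment report:")
print(f"  AUC pre-deployment:  {rep.auc_pre:.4f}")
print(f"  AUC post-deployment: {rep.auc_post:.4f}   (delta = {rep.delta_auc:+.4f})")
print(f"  self-fulfilling:     {rep.self_fulfilling}")
print(f"  harm by group:       x=0 {rep.harm_by_group[0].value}, "
      f"x=1 {rep.harm_by_group[1].value}")
print(f"  marginal verdict:    {rep.marginal_harm.value}")
print(f"  calibrated pre/post: {rep.calibrated_pre} / {rep.calibrated_post}")

print(
    "\nReading: withdrawing an effective treatment from the fast-growing group\n"
    "worsens their survival (harmful), which *widens* the outcome gap the\n"
    "model predicts — so its AUC improves. Good post-deployment\n"
    "discrimination here is evidence of harm, not of success."
)
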