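"""Finite-sample check of the closed-form machinery.

Samples a pre-deployment cohort under the historical policy and a
post-deployment cohort under the model-informed policy, then builds the
empirical deployment report (Mann-Whitney AUCs, two-proportion z-tests
for harm) and compares it with the exact closed-form report.
"""

from opmdeploy import (
    OutcomeModelParams,
    Polarity,
    ScenarioConfig,
    empirical_report,
    evaluate_scenario,
    fit_historical_opm,
    informed_policy,
    sample_cohort,
)

params = OutcomeModelParams(beta0=0.0, beta_x=1.0, beta_t=1.0, beta_xt=0.0, p_x=0.5)
scenario = ScenarioConfig(params=params, historical_policy=1,
                          polarity=Polarity.DESIRABLE)

opm = fit_historical_opm(params, scenario.pi0)
pif = informed_policy(opm)
n = 100_000
pre = sample_cohort(params, scenario.pi0, n=n, seed=20240101)
post = sample_cohort(params, pif, n=n, seed=20240102)

emp = empirical_report(pre, post, opm, scenario.polarity)
closed = evaluate_scenario(scenario)

print(f"cohorts: {n} patients each (pre under treat-everyone, post under "
      f"treat-{pif.assignment})")
print(f"{'':22s}{'empirical':>12s}{'closed form':>14s}")
print(f"{'AUC pre':22s}{emp.report.auc_pre:12.4f}{closed.auc_pre:14.4f}")
print(f"{'AUC post':22s}{emp.report.auc_post:12.4f}{closed.auc_post:14.4f}")
print(f"{'delta AUC':22s}{emp.report.delta_auc:12.4f}{closed.delta_auc:14.4f}")
print(f"{'marginal verdict':22s}{emp.report.marginal_harm.value:>12s}"
      f"{closed.marginal_harm.value:>14s}")
print(f"{'group x=0 verdict':22s}{emp.report.harm_by_group[0].value:>12s}"
      f"{closed.harm_by_group[0].value:>14s}")
print(f"{'calibrated post':22s}{str(emp.report.calibrated_post):>12s}"
      f"{str(closed.calibrated_post):>14s}")
print(f"\nz-test p-values per group: { {k: f'{v:.2g}' for k, v in emp.p_values_by_group.items()} }")
print(f"low-confidence flag: {emp.low_confidence}")
print(
    "\nReading: at this sample size the finite-sample report reproduces the\n"
    "closed-form verdicts; the harmed group's outcome drop is detected by\n"
    "the two-proportion test while the unchanged group stays neutral."
)
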