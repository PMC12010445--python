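"""Post-hoc audit of a deployed prediction model.

Given only three observable facts — whether Y=1 is desirable, whether
the historical policy treated everyone or no one, and which way the AUC
moved after deployment — the audit decides whether the deployment
harmed patients.  No counterfactual outcome data needed (but the
framework's assumptions must hold: constant historical policy,
covariate-dependent new policy, stable covariate mix).
"""

from opmdeploy import DeltaSign, Polarity, delta_sign, table1_audit

print("All eight audit cells:")
for polarity in Polarity:
    for pi0 in (1, 0):
        for sign in (DeltaSign.POSITIVE, DeltaSign.NEGATIVE):
            print("  " + table1_audit(polarity, pi0, sign).describe())

# A concrete case: a survival model deployed where everyone used to be
# treated; monitoring shows AUC went from 0.62 to 0.72.
print("\nConcrete case: AUC rose 0.62 -> 0.72, Y=1 desirable, was treat-everyone:")
verdict = table1_audit(Polarity.DESIRABLE, 1, delta_sign(0.72 - 0.62))
print("  " + verdict.describe())
print(
    "\nReading: the rising AUC looks like success, but with everyone\n"
    "previously treated, the score gap can only widen because the\n"
    "de-treated low-score group got worse — the deployment was harmful."
)
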