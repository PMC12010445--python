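# opmdeploy

**When does deploying an outcome prediction model cause harm that its own
post-deployment accuracy conceals?**

Clinical outcome prediction models (OPMs) are routinely fitted on historical
data and then used to allocate treatment: treat the patients whose predicted
outcome exceeds a threshold. But using a model to assign treatment *changes*
the outcome distribution it is later evaluated on. `opmdeploy` is a
closed-form calculator and simulator for this feedback loop in the simplest
world where it can be studied exactly — binary covariate X, binary treatment
T, binary outcome Y — aimed at biostatisticians, model-deployment auditors,
and anyone teaching why post-deployment AUC monitoring is not a safety net.

## The model

Outcomes follow a logistic potential-outcome model

```
X ~ Bernoulli(p_x)
T = π(X)                        (deterministic treatment policy)
Y ~ Bernoulli(σ(η)),   η = β₀ + βₓX + βₜT + βₓₜXT
```

The historical policy π₀ is constant (treat everyone, or no one). The OPM is
the infinite-data model fitted under π₀, i.e. `f(x) = p₀(Y=1|X=x)` — perfectly
calibrated on its training distribution. The informed policy π_f treats
exactly those with `f(x) > λ`. The package computes, in closed form:

- pre- and post-deployment AUC of `f` (for a two-level score,
  `AUC = ½ + [P(X=x_hi|Y=1) − P(X=x_hi|Y=0)]/2`, half credit for ties);
- whether the deployment is **self-fulfilling** (AUC does not decrease);
- whether it is **harmful** per covariate group and marginally: a group is
  harmed when its expected outcome strictly worsens, with "worse" read
  through the outcome polarity (Y=1 desirable vs. undesirable);
- pre-/post-deployment **calibration**, including the biconditional that an
  OPM calibrated before *and* after deployment changed nothing that matters;
- the **post-hoc audit**: harm inferred from polarity, historical rule and
  AUC direction alone;
- full **parameter sweeps** over the generative grid, and seeded
  **finite-cohort sampling** as the Monte Carlo mirror of every closed form.

## Worked example

A palliative-radiotherapy scenario (`examples/radiotherapy_scenario.py`):
historically everyone was treated; a survival model fitted on those records
is used to keep treating only the good-prognosis (slow-growing tumour)
group, but fast-growing tumours respond *better* to radiotherapy:

```
Treatment effect (risk difference) per group:
  fast-growing (x=0): +0.354
  slow-growing (x=1): +0.087
  average:            +0.220

OPM fitted on historical (everyone-treated) data:
  predicted survival: fast 0.731, slow 0.818
  threshold lambda = 0.774 -> treat groups with assignment (0, 1) (x=0, x=1)

Deployment report:
  AUC pre-deployment:  0.5619
  AUC post-deployment: 0.7287   (delta = +0.1668)
  self-fulfilling:     True
  harm by group:       x=0 harmful, x=1 neutral
  marginal verdict:    harmful
  calibrated pre/post: True / False
```

Withdrawing an effective treatment from the fast-growing group worsens their
survival — the deployment is harmful — yet that very worsening *widens* the
outcome gap the model predicts, so its AUC jumps by 0.17 and the deployment
looks like a success to anyone monitoring discrimination. The other examples
cover the post-hoc audit table (`audit_after_deployment.py`), the full
parameter sweep (`parameter_sweep.py`), and finite-sample verification of
the closed forms (`finite_cohorts.py`).

A thin CLI wraps the same calls:

```
opmdeploy report --scenario scenario.yaml
opmdeploy audit --polarity desirable --historical-policy 1 --delta-auc 0.08
opmdeploy sweep --out rows.csv [--grid grid.yaml] [--require-avg-beneficial]
```

Scenario files are YAML with keys `beta0, beta_x, beta_t, beta_xt, p_x,
historical_policy, polarity`.

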