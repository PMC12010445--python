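# Methods

## Setting and assumptions

`opmdeploy` analyses a deliberately minimal deployment world: one binary
covariate X, one binary treatment T, one binary outcome Y. Outcomes are
generated by a saturated logistic model on (X, T),

    p(Y^t = 1 | X = x) = σ(β₀ + βₓx + βₜt + βₓₜxt),

with X ~ Bernoulli(p_x). Three structural assumptions run through every
result and are enforced, not merely documented:

1. the historical policy π₀ is constant and deterministic (treat everyone or
   treat no one) — `fit_historical_opm` rejects anything else;
2. the OPM-informed policy π_f is *not* constant — configurations where it
   would be (tied scores, or a threshold outside the score range) raise
   `AssumptionViolationError` / `DegenerateOPMError` and are excluded from
   sweeps with a count, never silently processed;
3. the covariate marginal is the same pre- and post-deployment — automatic
   here, since policies only change treatment, and asserted as a property
   test.

Because π₀ is constant and π_f is not, exactly one covariate group changes
treatment at deployment. That single fact drives everything: the unchanged
group anchors the comparison, so subgroup harm and marginal harm always
agree, and every AUC movement is attributable to the changed group's outcome
shift.

## The OPM and its policy

The package works in the infinite-data limit: the fitted OPM is the
population conditional `f(x) = p₀(Y=1|X=x)` under the historical policy,
hence calibrated on historical data by construction. Finite-sample fitting
noise is deliberately out of scope — the sampling module exists to verify
the closed forms, not to estimate f. The informed policy treats iff
`f(x) > λ` (strict; ties at λ get no treatment). Any λ strictly between the
two scores induces the same policy, so the package's canonical threshold is
the midpoint of the two scores; threshold-invariance is asserted as a
property test rather than assumed.

## Closed-form AUC

For a two-level score the ROC curve has one interior vertex and the AUC of
f as a predictor of Y=1 is

    AUC = ½ + [P(X = x_hi | Y=1) − P(X = x_hi | Y=0)] / 2,

where x_hi is the higher-scored group; tied scores give ½ exactly. The
conditionals come from Bayes' rule on the policy-induced joint distribution.
AUC is computed for the score as a predictor of Y=1 regardless of polarity —
polarity only enters harm interpretation. Values below ½ are legitimate and
occur: post-deployment the score can rank worse than chance.

The empirical counterpart is the midrank Mann–Whitney statistic, which for
any score equals the fraction of case–control pairs ordered correctly with
half credit for ties; the test suite checks that identity against explicit
pair enumeration, and checks closed-vs-empirical agreement at n = 10⁵ using
the exact delta-method standard error
`SE = ½·√(a(1−a)/n₁ + b(1−b)/n₀)` with a, b the two conditional
probabilities above.

## Harm, self-fulfilling status, calibration

A deployment is *self-fulfilling* when AUC(post) ≥ AUC(pre). The boundary is
inclusive by definition, and a slack of 1e−12 protects exact-zero closed
forms from the last floating-point bit.

A group is *harmed* when its expected outcome strictly worsens, with the
inequality direction set by polarity; changes within 1e−9 on the probability
scale count as neutral (strict inequalities in the definition, and the only
exact zeros on the default grid are structural ones where βₜ + βₓₜx = 0).
Marginal harm is assessed on the p_x-weighted outcome change and provably
equals the changed group's verdict.

*Calibration* of f with respect to a distribution means E[Y | f(X)=α] = α at
every attained score level: per-group rate equality when scores are
distinct, pooled-rate equality when they tie. The package verifies
numerically, configuration by configuration, the biconditional that a
historically calibrated OPM stays calibrated post-deployment iff each
group's policy either did not change or changed where the treatment effect
is zero — i.e. post-deployment calibration certifies that the deployment was
inconsequential.

## The post-hoc audit

When the three assumptions hold, three observable facts — polarity,
historical rule, sign of the AUC change — determine whether the deployment
was harmful. The anchor cell: Y=1 desirable, historically treat-everyone,
AUC rose ⇒ harmful (the de-treated low-score group must have got worse for
the score gap to widen); the other seven cells follow by flipping the
historical rule or the polarity. An exactly-zero AUC change is reported as
*indeterminate*: the table's logic uses strict signs and the package refuses
to extrapolate. The audit is validated against ground truth on every sweep
row with a signed AUC change, covering all eight cells.

## The parameter sweep

The default grid takes each β from {−2, −1.5, …, 2} (odds ratios ≈ 0.14–7.4,
i.e. moderate clinical effect sizes without extremes), p_x from
{0.1, 0.25, 0.5, 0.75, 0.9}, both constant historical policies and both
polarities: 131,220 configurations, of which those with a constant informed
policy (βₓ + βₓₜ·t₀ = 0) are excluded and counted. Everything is closed
form, so the sweep is deterministic and runs in seconds; identical grids
produce byte-identical CSVs. An optional filter keeps only configurations
whose average treatment effect is strictly positive — the realistic regime,
since treatments generally reach the market only after average benefit is
shown in an RCT. Odds-ratio columns (e^βₜ, e^βₓₜ) and the average effect are
stored per row so the standard four-panel scatter (AUC change vs. effect
odds ratio, per polarity × historical rule) can be redrawn from the CSV;
`plot_sweep` is a thin optional layer over matplotlib.

On this grid the maximum AUC increase among harmful self-fulfilling
deployments is computed from scratch by `scripts/acceptance.py`; the sweep
summary also counts the dual "beneficial self-defeating" rows, where a
deployment improves outcomes and thereby *lowers* AUC.

## Synthetic cohorts

`sample_cohort` implements the generative process verbatim — x ~ B(p_x),
t = π(x), y ~ B(σ(η)) — with a mandatory explicit seed (the test fixtures
use 20240101). It emulates exactly the stated Bernoulli/logistic world and
nothing more: no covariate richness, no missingness, no censoring, no
non-compliance with the policy. Passing finite-sample checks therefore
demonstrates the internal consistency of the closed forms, not robustness of
the audit logic to real-data violations of the assumptions (drifting
covariate mix, non-constant historical policies), which the package
explicitly refuses to audit.

`empirical_report` mirrors the closed-form report from two cohorts:
Mann–Whitney AUCs, per-group harm via two-proportion z-tests at α = 0.05
(statsmodels), and calibration by comparing group rates to scores within an
absolute tolerance (default 0.02). The z-tests are a reporting heuristic —
the distributional definitions remain the ground truth — and verdicts are
flagged low-confidence when any per-group cell has fewer than 30 patients.
Convergence of empirical verdicts to the closed-form ones is tested at
n ∈ {10³, 10⁴, 10⁵}.

## Numerical choices and degenerate inputs

- Probabilities are carried as double-precision closed forms; σ is computed
  in its numerically stable branch form. Parameters so extreme that a
  probability rounds to exactly 0 or 1 are rejected, preserving the strict
  non-degeneracy all closed forms rely on.
- Group labels are fixed to {0, 1}; continuous or categorical covariates,
  stochastic or time-varying policies, and non-binary outcomes are out of
  scope by design.
- Problem sizes: the default sweep (131,220 configurations) and Monte Carlo
  checks at n = 10⁵–10⁶ were chosen so the full suite and the acceptance
  script each run in well under a minute of compute on one CPU while keeping
  binomial standard errors an order of magnitude below every margin being
  checked.

## Known limitations

The theory this package operationalises is intentionally a minimal model.
Real deployments involve continuous risk scores, non-threshold clinician
behaviour, partial compliance, covariate drift, and historical policies that
already depended on the covariate — all outside the audit's validity. The
worked radiotherapy scenario uses parameters chosen here for pedagogical
clarity; it illustrates the mechanism and does not claim to match any
published cohort.
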