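# Methods

`edcounts` models per-person counts of emergency-department (ED) visits
over a fixed follow-up window. Such outcomes are characterized by a heavy
zero mass (most respondents of a general-population survey never visit),
overdispersion (conditional variance far above the conditional mean), and
a long right tail (a small group of frequent users). The package implements
the six regression families conventionally compared in this setting, fits
them by direct maximum likelihood, and adjudicates between them with the
Vuong non-nested likelihood-ratio test.

## Model families

Let `y_i` be the visit count of respondent `i`, `x_i` the count-component
covariate row and `z_i` the zero-component covariate row (equal by default).

* **Poisson** — `P(y) = e^{-mu} mu^y / y!` with `mu_i = exp(x_i beta)`.
  Equidispersed: `Var = mu`.
* **Negative binomial (NB2)** — gamma heterogeneity in the Poisson rate is
  integrated out analytically, giving `Var = mu + v mu^2` with dispersion
  `v > 0`. As `v -> 0` the NB converges to the Poisson.
* **Zero-inflated (ZIP / ZINB)** — a two-class mixture: with probability
  `psi_i` the respondent belongs to a never-user class (structural zero);
  otherwise counts follow the Poisson/NB density, which contributes
  additional sampling zeros. Conditional moments:
  `E = mu(1-psi)`, `Var = mu(1-psi)(1+mu psi)` (ZIP) and
  `mu(1-psi)(1+mu(psi+v))` (ZINB).
* **Hurdle (HP / HNB)** — `psi_i` is the *total* zero probability; positive
  counts follow the zero-truncated Poisson/NB density with normalizers
  `1 - e^{-mu}` and `1 - (1+v mu)^{-1/v}`. Hurdle moments are not usually
  printed in textbook form; we derive them from the truncated density's
  first two moments via the law of total variance and validate them against
  numeric summation in the tests.

Useful identities used as exact test oracles: a hurdle model whose zero
probability equals the parent density's zero mass *is* the parent
(`HP(psi=e^{-mu}) = Poisson`, `HNB(psi=(1+v mu)^{-1/v}) = NB`), and
zero-inflated families collapse to their parents as `psi -> 0`.

### Sign convention for the zero component

Both components are linked canonically: `mu = exp(x beta)` and
`psi = expit(z gamma)`. Some presentations write the zero-probability
logistic with the opposite sign (`psi = 1/(1+e^{z gamma})`, *decreasing* in
the linear predictor); we deliberately use the mainstream orientation, so
`gamma` coefficients flip sign relative to such presentations. Because
`psi` points at the *zero* state, the reporting layer (`effect_table`)
negates binary-component coefficients before exponentiating: **all odds
ratios in output describe the odds of at least one visit**, so an OR below
one means lower odds of any utilization — the direction practitioners
expect (for ZIP/ZINB the binary component is the structural-zero class, so
the OR describes the odds of *not* being a never-user).

## Estimation

All six log-likelihoods are maximized directly (the I(y=0)/I(y>=1)
branches implemented in log space with log-gamma and log-sum-exp; no
finite intermediate under/overflow for `y <= 1e6`, `mu <= 1e4`).
Probabilities are floored at `exp(-745)` before logging so optimizer
excursions produce large finite penalties rather than `-inf`.

* **Starting values.** `beta` from a small self-contained Poisson IRLS,
  `gamma` from a logistic IRLS on the indicator `y == 0`, and
  `v = max((s^2 - ybar)/ybar^2, 0.01)` by method of moments.
* **Optimizer.** BFGS with analytic score functions (derived per family;
  checked against central finite differences to ~1e-8 in the tests), run
  from the data-driven start plus `n_starts - 1` Gaussian-jittered
  restarts (sd `= jitter_scale (1 + |start|)`, seeded); the best optimum
  is kept. The dispersion is optimized as `log v`, enforcing positivity.
* **Convergence.** Declared only when the max-norm of the gradient of the
  *mean* per-observation log-likelihood is below `gradient_tol` (default
  `1e-5`) **and** the negated Hessian admits a Cholesky factorization.
  Measuring the gradient per observation makes the tolerance scale-free
  in the sample size. The Hessian is a central-difference Jacobian of the
  analytic score.
* **Inference.** `vcov` is the inverse negative Hessian of the total
  log-likelihood; Wald intervals use `z = Phi^{-1}(0.975) = 1.959964`;
  p-values are two-sided normal. Dispersion uncertainty lives on the
  `log v` coordinate.
* **Weights.** Likelihoods are unweighted by default — sampling weights
  conventionally enter the descriptive tables only; a weighted-likelihood
  switch exists (`fit(..., weights=...)`, equivalent to row replication).

## Model comparison

For models 1 and 2 fitted to the same rows,
`m_i = ln f1(y_i) - ln f2(y_i)`, `V = sqrt(N) m_bar / s_m` with the
`n-1`-denominator sample standard deviation, asymptotically `N(0,1)` under
equivalence. No AIC/BIC-style parameter correction is applied. The default
critical value is `1.96` (`alpha = 0.05`) and configurable. The 6x6 matrix
is lower-triangular in the canonical order (Poisson, NB, ZIP, ZINB, HP,
HNB) and oriented so a **negative** cell means the **row** model fits
significantly better than the column model.

`select_best` picks the model that is never significantly beaten and beats
the most rivals. Ties break first toward fewer parameters; among equally
parameterized, statistically indistinguishable candidates (in practice a
hurdle model and its zero-inflated twin) the tie breaks toward the hurdle
variant. This is a substantive choice, not a statistical one: when fits are
equivalent, the hurdle description — whose zeros have a single
interpretable source (the decision not to seek care) — is the preferred
account of utilization data, whereas zero-inflated zeros mix structural
and sampling sources. A tie-broken or unbeaten-less selection is flagged
`ambiguous`, and the full pairwise trace is always attached.

A caution surfaced by the synthetic experiments: when the hurdle zero
probability exceeds the count density's zero mass everywhere (strong
inflation), an HNB is *exactly* representable by a ZINB at identical
likelihood in the intercept-only case and nearly so with covariates, so
HNB-vs-ZINB comparisons are genuinely inconclusive at moderate n; at small
n the ZINB's zero channel (coupled to `mu` and `v` through its p0 term) can
even win in sample. Distinguishability requires either large samples or
zero-*deflated* subgroups (zero probability below the NB zero mass), which
only the hurdle can represent.

## Synthetic cohort generator

The generator emulates a two-cycle population health survey linked to ED
visit records: ~26,700 respondents per cycle; ten categorical covariates
(gender, age group, household income, education, chronic-condition count,
self-rated health, ambulatory-diagnostic-group category,
resource-utilization band, access to a regular doctor, rurality) drawn
independently from configured marginals; unit sampling weights; and two
outcome counts (high-severity, triage 1-3; low-severity, triage 4-5) drawn
*exactly* from a configured family's pmf given the true coefficients.

* **Shipped truth.** Hurdle-NB in both strata with `v = 1.3` (high) and
  `1.5` (low). Effect directions follow the utilization gradients typical
  of ED-demand studies (worse health, lower income/education, higher
  expected-resource-use raise both the odds and the rate of visiting);
  magnitudes are round numbers and are not claimed to reproduce any fitted
  study. Access to a regular doctor is a pure low-severity effect
  (utilization OR 0.69, rate ratio 0.57; exactly null in the high-severity
  stratum), giving the pipeline a known stratified contrast to recover.
  Intercepts were calibrated once, numerically, at design time so the
  population zero fractions are ~0.885 (high) and ~0.855 (low) and the
  mean count among users is ~1.5 — with the result that just over 75% of
  simulated respondents never visit at all.
* **Sampling.** Zero-inflated draws mix a Bernoulli structural-zero with
  Poisson or gamma-mixture NB draws. Hurdle positives use sequential
  inverse-CDF search over `y = 1, 2, ...` through the zero-truncated CDF —
  exact, with no rejection-rate pathology at small `mu` — capped at
  `y_max = 10,000` (cap hits are resampled with a warning).
* **Seeding.** One master seed is split into name-keyed substreams (CRC32
  of the column/outcome label) so adding a covariate never perturbs other
  columns, and identical configs give byte-identical cohorts.
* **What it does not emulate.** Covariates are sampled independently (only
  marginals are configured), so real-data covariate correlation, survey
  design effects (strata, clusters, calibrated weights), visit-level
  records, and within-person correlation beyond what the shared covariates
  induce are absent. Passing tests therefore demonstrate correctness of
  the machinery under a known data-generating process, not robustness to
  the messiness of real linked survey data.

## Pipeline

`run_study` loads or generates a cohort (pooled cycles are emulated by
concatenating independently generated cohorts; no cycle term is added, and
respondents with zero visits are retained in both strata), treatment-codes
the predictors against fixed reference levels (female, age 65+, RUB 0-1,
ADG 0-5, high income, high education, excellent/very-good self-rated
health, no regular doctor, no chronic condition, urban), fits the requested
families per stratum, writes effect tables (with reference rows marked,
ratio 1), Vuong matrices (CSV and annotated text), the selection trace and
run metadata. File names and column orders are frozen for
regression-testing; reruns with the same seed are byte-identical. Stage
failures are recorded per family and the report is still emitted.

## Problem sizes and defaults

Desk-scale defaults were chosen so the complete test suite and the
acceptance script each run in a few minutes on one core: the shipped study
runs two cycles of 4,000 respondents by default, and the acceptance script
uses 10,000 per cycle (the survey-scale generator default of 26,693 per
cycle is used where only simulation, not fitting, is required). These are
also the scales at which the selection experiment stabilizes — at smaller
sizes the ZINB twin occasionally beats the true hurdle model *in sample*
(see the caution above). Simulation-based checks use 50-100 replicates at
n = 5,000.

## Known limitations

* Wald inference only: no sandwich/robust variances, likelihood-ratio
  intervals, or survey-bootstrap variance.
* The Vuong statistic is used in its uncorrected form; strictly, comparing
  overlapping (partially nested) families with it is a pragmatic
  convention of the applied literature rather than the fully general
  theory.
* Numerically differenced Hessians can fail the definiteness check on
  near-nonidentifiable fits (e.g. a zero-inflated model pushed toward its
  boundary); such fits are reported with `converged = False` and no
  covariance rather than silently accepted.
* The gamma heterogeneity of the NB is integrated out analytically; no
  right-censored hurdle variants or multilevel extensions are provided.
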