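# edcounts

Count-data regression for health-services utilization studies: six
maximum-likelihood model families (Poisson, negative binomial,
zero-inflated Poisson/NB, hurdle Poisson/NB), effect tables with rate and
odds ratios, Vuong non-nested model comparison, and a synthetic
survey-cohort generator so every stage is testable end to end.

## The problem

Annual counts of emergency-department (ED) visits in a general-population
survey are awkward for ordinary regression: 75-90% of respondents record
zero visits, the variance far exceeds the mean, and a small group of
frequent users stretches the right tail. Epidemiologists analyzing who
visits, and how often, therefore compare a ladder of count models:

* **Poisson**: `P(y | x) = e^{-mu} mu^y / y!`, `mu = exp(x beta)`,
  `Var = mu`;
* **Negative binomial (NB2)**: gamma-distributed rate heterogeneity,
  `Var = mu + v mu^2`;
* **Zero-inflated (ZIP/ZINB)**: a never-user class of probability
  `psi = expit(z gamma)` mixed with a Poisson/NB count class;
* **Hurdle (HP/HNB)**: `psi` is the total zero probability and positive
  counts follow the zero-truncated Poisson/NB density, normalized by
  `1 - e^{-mu}` or `1 - (1 + v mu)^{-1/v}`.

Exponentiated count-component coefficients are **rate ratios** (RR);
binary-component coefficients are reported as **odds ratios** (OR) for the
odds of *at least one visit* (see `docs/methods.md` for the sign
convention). Competing fits are compared with the **Vuong statistic**
`V = sqrt(N) m_bar / s_m` over per-observation log-likelihood differences
`m_i`, asymptotically N(0,1) under model equivalence; `|V| > 1.96` favors
one model at the 5% level.

The package is aimed at biostatisticians and health-services researchers
who want these families, their comparison machinery, and a reproducible
synthetic cohort in one tested toolkit — the study design it reproduces
(severity-stratified ED visit counts linked to survey covariates) relies
on confidential linked microdata, so the generator stands in with known
ground truth.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from edcounts import (default_config, make_study_dataset, FamilySpec, Family,
                      fit, FitOptions, effect_table, vuong)
from edcounts.design import code_predictors, DEFAULT_REFERENCE_LEVELS

# synthetic survey cohort: 8,000 respondents, hurdle-NB ground truth
cohort = make_study_dataset(default_config(n=8000, seed=42))
print("zero fraction, low severity:", round((cohort.y_low == 0).mean(), 3))

design, _ = code_predictors(cohort, DEFAULT_REFERENCE_LEVELS)
frame = design.copy(); frame["y_low"] = cohort["y_low"]
terms = tuple(design.columns)

hnb = fit(FamilySpec(Family.HNB, count_design=terms, zero_design=terms),
          frame, "y_low", FitOptions(n_starts=2, seed=0))
pois = fit(FamilySpec(Family.POISSON, count_design=terms),
           frame, "y_low", FitOptions(n_starts=2, seed=0))

tab = effect_table(hnb).set_index(["component", "term"])
r, c = tab.loc[("binary", "doctor_yes")], tab.loc[("count", "doctor_yes")]
print(f"doctor access OR {r['ratio']:.2f} (95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f})")
print(f"doctor access RR {c['ratio']:.2f} (95% CI {c['ci_low']:.2f}-{c['ci_high']:.2f})")
v = vuong(pois, hnb)
print(f"Vuong Poisson vs HNB: V = {v.V:.2f} -> {v.decision}")
```

prints

```
zero fraction, low severity: 0.849
doctor access OR 0.64 (95% CI 0.52-0.79)
doctor access RR 0.52 (95% CI 0.40-0.67)
Vuong Poisson vs HNB: V = -11.94 -> favor_model2
```

Read: 84.9% of simulated respondents had no low-severity visit; having a
regular doctor lowers the odds of any low-severity visit by ~36% and the
visit rate among users by ~48% (the generator's truth is OR 0.69 /
RR 0.57, well inside the intervals); and the Vuong statistic decisively
rejects the Poisson in favor of the hurdle-NB (`favor_model2` = the second
argument).

The full pipeline — weighted descriptives, per-stratum fits of all six
families, Vuong matrices and model selection, everything written as
CSV/JSON — runs with

```bash
edcounts run-study --n-per-cycle 4000 --seed 1 --out study_out/
```

(`edcounts simulate`, `edcounts fit` and `edcounts compare` expose the
individual stages.)

## Layout

```
src/edcounts/families.py   densities, log-likelihoods, links, moments
src/edcounts/estimate.py   ML fitting (multi-start BFGS, analytic scores), effect tables
src/edcounts/vuong.py      Vuong test, comparison matrix, model selection
src/edcounts/simulate.py   synthetic cohort generator with known truth
src/edcounts/design.py     treatment coding of categorical predictors
src/edcounts/pipeline.py   end-to-end study driver and report artifacts
src/edcounts/cli.py        command-line interface
docs/methods.md            models, conventions, numerical choices, limitations
```
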