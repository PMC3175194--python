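"""Maximum-likelihood fitting: oracles, gradients, inference, invariants."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from edcounts.families import Family, FamilySpec, ParameterSet
from edcounts.estimate import (
    FitOptions,
    FitResult,
    _loglik_and_score,
    _pack,
    effect_table,
    fit,
    starting_values,
)
from edcounts.simulate import simulate_outcomes

ALL_FAMILIES = ["poisson", "nb", "zip", "zinb", "hp", "hnb"]


def _spec_and_params(family):
    fam = Family(family)
    spec = FamilySpec(fam, count_design=("x1", "x2"),
                      zero_design=("x1", "x2") if fam.has_zero_component else ())
    params = ParameterSet(
        beta=[0.2, 0.3, -0.4],
        gamma=[0.5, -0.6, 0.8] if fam.has_zero_component else None,
        v=0.7 if fam.has_dispersion else None)
    return spec, params


# ---------------------------------------------------------------------------
# closed-form and reference oracles


def test_intercept_only_poisson_mle_is_log_mean():
    df = pd.DataFrame({"y": [2, 0, 1, 3, 0]})
    fr = fit(FamilySpec(Family.POISSON), df, "y", FitOptions(n_starts=1))
    assert fr.params.beta[0] == pytest.approx(np.log(1.2), abs=1e-8)
    y = df["y"].to_numpy()
    mu = 1.2
    import math
    expected = np.sum(-mu + y * np.log(mu)
                      - np.log([math.factorial(int(k)) for k in y]))
    assert fr.loglik == pytest.approx(expected, abs=1e-8)
    assert fr.converged


def test_poisson_fit_matches_reference_glm(small_cohort):
    spec = FamilySpec(Family.POISSON, count_design=("x1", "x2"))
    fr = fit(spec, small_cohort, "y_pois", FitOptions(n_starts=3, seed=0))
    X = sm.add_constant(small_cohort[["x1", "x2"]])
    ref = sm.GLM(small_cohort["y_pois"], X, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(fr.params.beta, ref.params.values, atol=1e-4)
    # Wald SEs agree too
    np.testing.assert_allclose(np.sqrt(np.diag(fr.vcov)), ref.bse.values,
                               rtol=1e-3)


def test_nb_fit_matches_reference_mle(small_cohort):
    spec = FamilySpec(Family.NB, count_design=("x1", "x2"))
    fr = fit(spec, small_cohort, "y_nb", FitOptions(n_starts=3, seed=0))
    X = sm.add_constant(small_cohort[["x1", "x2"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = sm.NegativeBinomial(small_cohort["y_nb"], X).fit(
            disp=0, maxiter=500)
    np.testing.assert_allclose(fr.params.beta, ref.params.values[:3], atol=1e-4)
    assert fr.params.v == pytest.approx(ref.params.values[3], abs=1e-4)


def test_zip_fit_matches_reference_mle(small_cohort):
    from statsmodels.discrete.count_model import ZeroInflatedPoisson

    df = small_cohort.copy()
    spec = FamilySpec(Family.ZIP, count_design=("x1", "x2"),
                      zero_design=("x1", "x2"))
    truth = ParameterSet(beta=[0.8, 0.3, -0.4], gamma=[-0.4, 0.5, 0.3])
    df["y"] = simulate_outcomes(df[["x1", "x2"]], spec, truth, seed=21)
    fr = fit(spec, df, "y", FitOptions(n_starts=3, seed=0))
    X = sm.add_constant(df[["x1", "x2"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = ZeroInflatedPoisson(df["y"], X, exog_infl=X).fit(
            disp=0, maxiter=500, method="bfgs")
    # statsmodels orders inflation params first; same psi orientation
    np.testing.assert_allclose(fr.params.gamma, ref.params.values[:3], atol=2e-3)
    np.testing.assert_allclose(fr.params.beta, ref.params.values[3:], atol=2e-3)


# ---------------------------------------------------------------------------
# analytic scores


@pytest.mark.parametrize("family", ALL_FAMILIES)
def test_analytic_score_matches_finite_differences(family):
    rng = np.random.default_rng(17)
    n = 150
    df = pd.DataFrame({"x1": rng.normal(size=n),
                       "x2": rng.integers(0, 2, n).astype(float)})
    spec, params = _spec_and_params(family)
    y = simulate_outcomes(df, spec, params, seed=5).astype(float)
    X = np.column_stack([np.ones(n), df["x1"], df["x2"]])
    Z = X if spec.family.has_zero_component else None
    w = np.ones(n)
    theta = _pack(spec, params) + rng.normal(size=spec.n_params) * 0.1
    _, score, _ = _loglik_and_score(spec, theta, y, X, Z, w)
    num = np.zeros_like(theta)
    for j in range(len(theta)):
        h = 1e-6 * (1 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        num[j] = (_loglik_and_score(spec, tp, y, X, Z, w)[0]
                  - _loglik_and_score(spec, tm, y, X, Z, w)[0]) / (2 * h)
    np.testing.assert_allclose(score, num, rtol=1e-5, atol=1e-5)


# ---------------------------------------------------------------------------
# starting values and degenerate inputs


def test_starting_values_rules(small_cohort):
    # equidispersed data floors the dispersion start
    df = pd.DataFrame({"y": np.random.default_rng(0).poisson(2.0, 500)})
    sv = starting_values(FamilySpec(Family.NB), df, "y")
    assert sv.v == pytest.approx(0.01) or sv.v < 0.2
    # intercept-only Poisson start is log(mean)
    sv2 = starting_values(FamilySpec(Family.POISSON), df, "y")
    assert sv2.beta[0] == pytest.approx(np.log(df["y"].mean()), abs=1e-6)


def test_all_zero_outcome_rejected():
    df = pd.DataFrame({"y": [0, 0, 0, 0]})
    with pytest.raises(ValueError, match="positive"):
        starting_values(FamilySpec(Family.POISSON), df, "y")


def test_rank_deficient_design_rejected():
    df = pd.DataFrame({"a": [1.0, 0.0, 1.0, 0.0], "b": [1.0, 0.0, 1.0, 0.0],
                       "y": [1, 2, 0, 3]})
    with pytest.raises(np.linalg.LinAlgError, match="rank"):
        starting_values(FamilySpec(Family.POISSON, count_design=("a", "b")),
                        df, "y")


# ---------------------------------------------------------------------------
# fit invariants


@pytest.fixture(scope="module")
def hurdle_cohort():
    rng = np.random.default_rng(99)
    n = 2000
    df = pd.DataFrame({"x1": rng.normal(size=n) * 0.5,
                       "x2": rng.integers(0, 2, n).astype(float)})
    spec = FamilySpec(Family.HNB, count_design=("x1", "x2"),
                      zero_design=("x1", "x2"))
    truth = ParameterSet(beta=[0.4, 0.3, -0.2], gamma=[0.8, -0.4, 0.3], v=0.9)
    df["y"] = simulate_outcomes(df, spec, truth, seed=31)
    return df


def test_nested_dispersion_dominance(hurdle_cohort):
    """The NB-dispersion member of each pair can never fit worse at the
    optimum than its equidispersed counterpart."""
    results = {}
    for fam in ["zip", "zinb", "hp", "hnb"]:
        f = Family(fam)
        spec = FamilySpec(f, count_design=("x1", "x2"), zero_design=("x1", "x2"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results[fam] = fit(spec, hurdle_cohort, "y",
                               FitOptions(n_starts=2, seed=0))
    assert results["zinb"].loglik >= results["zip"].loglik - 1e-6
    assert results["hnb"].loglik >= results["hp"].loglik - 1e-6


def test_start_robustness(hurdle_cohort):
    """Different jitter seeds land on the same optimum."""
    spec = FamilySpec(Family.HNB, count_design=("x1", "x2"),
                      zero_design=("x1", "x2"))
    lls = [fit(spec, hurdle_cohort, "y",
               FitOptions(n_starts=3, seed=s)).loglik for s in (0, 1)]
    assert abs(lls[0] - lls[1]) < 1e-4


def test_weighting_equals_row_duplication(small_cohort):
    spec = FamilySpec(Family.POISSON, count_design=("x1", "x2"))
    w = np.ones(len(small_cohort))
    w[:50] = 2.0
    fr_w = fit(spec, small_cohort, "y_pois", FitOptions(n_starts=1), weights=w)
    dup = pd.concat([small_cohort, small_cohort.iloc[:50]], ignore_index=True)
    fr_d = fit(spec, dup, "y_pois", FitOptions(n_starts=1))
    np.testing.assert_allclose(fr_w.params.beta, fr_d.params.beta, atol=1e-6)


# ---------------------------------------------------------------------------
# effect tables


def _dummy_fit(theta, se, names, family=Family.HNB):
    spec = FamilySpec(family, count_design=(), zero_design=())
    k = len(theta)
    return FitResult(
        spec=spec, params=ParameterSet(beta=[0.0], gamma=[0.0], v=1.0),
        loglik=0.0, per_obs_loglik=np.zeros(1),
        vcov=np.diag(np.asarray(se) ** 2), gradient_norm=0.0,
        hessian_neg_definite=True, converged=True, n_obs=1, n_params=k,
        theta=np.asarray(theta, dtype=float), param_names=list(names))


def test_effect_table_ci_arithmetic():
    """exp(0.5 +/- 1.959964 * 0.1) = (1.35528, 2.00573) around 1.64872."""
    fr = _dummy_fit([0.5], [0.1], ["count:x"])
    row = effect_table(fr).iloc[0]
    assert row["ratio"] == pytest.approx(np.exp(0.5), abs=1e-4)
    assert row["ci_low"] == pytest.approx(np.exp(0.5 - 1.959964 * 0.1), abs=1e-6)
    assert row["ci_high"] == pytest.approx(np.exp(0.5 + 1.959964 * 0.1), abs=1e-6)
    assert row["ci_low"] == pytest.approx(1.35528, abs=1e-4)
    assert row["ci_high"] == pytest.approx(2.00573, abs=1e-4)


def test_effect_table_null_coefficient():
    fr = _dummy_fit([0.0], [0.2], ["count:x"])
    row = effect_table(fr).iloc[0]
    assert row["ratio"] == pytest.approx(1.0)
    # CI symmetric around 1 on the log scale
    assert np.log(row["ci_low"]) == pytest.approx(-np.log(row["ci_high"]))
    assert row["ci_low"] < 1.0 < row["ci_high"]


def test_binary_component_oriented_to_utilization_odds():
    """gamma raises P(zero); the table reports odds of >=1 visit, so the
    displayed OR is exp(-gamma): +0.371064 on the zero scale shows 0.690."""
    fr = _dummy_fit([0.1, 0.371064], [0.1, 0.05],
                    ["binary:intercept", "binary:doctor_yes"])
    row = effect_table(fr).set_index("term").loc["doctor_yes"]
    assert row["component"] == "binary"
    assert row["ratio"] == pytest.approx(0.690, abs=5e-4)
    assert row["ci_low"] < row["ratio"] < row["ci_high"]


def test_effect_table_requires_vcov():
    fr = _dummy_fit([0.5], [0.1], ["count:x"])
    fr.vcov = None
    with pytest.raises(ValueError, match="covariance"):
        effect_table(fr)


def test_hnb_parameter_recovery_moderate_n():
    """All coefficients recovered within 3 reported SEs at n=8000."""
    spec = FamilySpec(Family.HNB, count_design=("x1", "x2"),
                      zero_design=("x1", "x2"))
    truth = ParameterSet(beta=[0.1, 0.4, -0.3], gamma=[1.0, -0.8, 0.5], v=0.8)
    rng = np.random.default_rng(13)
    n = 8000
    df = pd.DataFrame({"x1": (rng.uniform(size=n) < 0.4).astype(float),
                       "x2": (rng.uniform(size=n) < 0.25).astype(float)})
    df["y"] = simulate_outcomes(df, spec, truth, seed=rng)
    fr = fit(spec, df, "y", FitOptions(n_starts=2, seed=0))
    assert fr.converged
    truth_theta = np.concatenate([truth.beta, truth.gamma, [np.log(truth.v)]])
    z = (fr.theta - truth_theta) / np.sqrt(np.diag(fr.vcov))
    assert np.all(np.abs(z) < 3)
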