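"""Direct maximum-likelihood estimation of the six count-model families.

The log-likelihoods of :mod:`edcounts.families` are maximized numerically
(quasi-Newton BFGS with analytic score functions) from data-driven starting
values plus jittered restarts; the best converged optimum is retained.
Convergence is declared only when the gradient of the *mean* per-observation
log-likelihood has max-norm below tolerance **and** the negated Hessian is
positive definite (checked via Cholesky), mirroring the practice of
inspecting final gradients and Hessians when likelihoods are maximized
directly.  The covariance of the estimates is the inverse negative Hessian
of the total log-likelihood at the optimum.

The NB dispersion ``v`` (Var = mu + v*mu^2) is optimized on the log scale,
which enforces ``v > 0``.  The zero-component probability ``psi`` is
logistic in its linear predictor and oriented toward the *zero* state;
:func:`effect_table` flips the sign of binary-component coefficients before
exponentiating, so reported odds ratios always describe the odds of at
least one visit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit
from scipy.stats import norm

from .families import (
    Family,
    FamilySpec,
    ParameterSet,
    _log1mexp,
    _nb_logp0,
    design_matrix,
    logpmf,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "starting_values",
    "fit",
    "effect_table",
]


@dataclass
class FitOptions:
    """Multi-start optimization settings.

    ``gradient_tol`` bounds the max-norm of the mean log-likelihood
    gradient at a declared optimum; ``jitter_scale`` controls the Gaussian
    perturbation (sd = jitter_scale * (1 + |start|)) of restarts.
    """

    n_starts: int = 5
    gradient_tol: float = 1e-5
    max_iter: int = 500
    jitter_scale: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_starts < 1 or self.gradient_tol <= 0 or self.max_iter < 1 \
                or self.jitter_scale <= 0:
            raise ValueError("all FitOptions fields must be positive")


@dataclass
class FitResult:
    spec: FamilySpec
    params: ParameterSet
    loglik: float
    per_obs_loglik: np.ndarray
    vcov: np.ndarray | None
    gradient_norm: float
    hessian_neg_definite: bool
    converged: bool
    n_obs: int
    n_params: int
    theta: np.ndarray = field(repr=False, default=None)
    param_names: list = field(default_factory=list)
    n_starts_converged: int = 0

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


# ---------------------------------------------------------------------------
# parameter packing


def _param_layout(spec: FamilySpec):
    names = ["count:intercept"] + [f"count:{t}" for t in spec.count_design]
    k_beta = len(names)
    k_gamma = 0
    if spec.family.has_zero_component:
        names += ["binary:intercept"] + [f"binary:{t}" for t in spec.zero_design]
        k_gamma = 1 + len(spec.zero_design)
    if spec.family.has_dispersion:
        names.append("log_v")
    return names, k_beta, k_gamma


def _pack(spec: FamilySpec, params: ParameterSet) -> np.ndarray:
    parts = [params.beta]
    if spec.family.has_zero_component:
        parts.append(params.gamma)
    if spec.family.has_dispersion:
        parts.append([np.log(params.v)])
    return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])


def _unpack(spec: FamilySpec, theta: np.ndarray) -> ParameterSet:
    _, k_beta, k_gamma = _param_layout(spec)
    beta = theta[:k_beta]
    gamma = theta[k_beta:k_beta + k_gamma] if k_gamma else None
    v = float(np.exp(theta[-1])) if spec.family.has_dispersion else None
    return ParameterSet(beta=beta.copy(),
                        gamma=None if gamma is None else gamma.copy(), v=v)


# ---------------------------------------------------------------------------
# IRLS starting fits (kept deliberately small and self-contained)


def _check_full_rank(X: np.ndarray, names) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, rr = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(rr[j, j]) < 1e-8 * max(1.0, abs(rr[0, 0]))]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"suspect columns: {bad or 'unknown'}"
        )


def _irls(X, y, kind: str, w=None, n_iter: int = 30, tol: float = 1e-8):
    """Minimal IRLS for Poisson (log link) or Bernoulli (logit link)."""
    n, k = X.shape
    w = np.ones(n) if w is None else w
    beta = np.zeros(k)
    if kind == "poisson":
        beta[0] = np.log(max(np.average(y, weights=w), 1e-8))
    ridge = 1e-8 * np.eye(k)
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        if kind == "poisson":
            mu = np.exp(eta)
            W = w * mu
            z = eta + (y - mu) / mu
        else:
            p = np.clip(expit(eta), 1e-10, 1 - 1e-10)
            W = w * p * (1 - p)
            z = eta + (y - p) / (p * (1 - p))
        XtW = X.T * W
        new = np.linalg.solve(XtW @ X + ridge, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def starting_values(spec: FamilySpec, cohort: pd.DataFrame, outcome: str,
                    weights=None) -> ParameterSet:
    """Data-driven starts: Poisson IRLS for beta, logistic IRLS on the
    zero indicator for gamma, method-of-moments for v (floored at 0.01)."""
    y = cohort[outcome].to_numpy(dtype=float)
    if not np.any(y > 0):
        raise ValueError("outcome has no positive counts; count component "
                         "cannot be anchored")
    X = design_matrix(cohort, spec.count_design)
    names, _, _ = _param_layout(spec)
    _check_full_rank(X, names)
    beta = _irls(X, y, "poisson", w=weights)
    gamma = None
    if spec.family.has_zero_component:
        Z = design_matrix(cohort, spec.zero_design)
        _check_full_rank(Z, [f"binary:{t}" for t in ("intercept",) + spec.zero_design])
        gamma = _irls(Z, (y == 0).astype(float), "logistic", w=weights)
    v = None
    if spec.family.has_dispersion:
        ybar = y.mean()
        s2 = y.var(ddof=1) if len(y) > 1 else ybar
        v = max((s2 - ybar) / ybar ** 2, 0.01)
    return ParameterSet(beta=beta, gamma=gamma, v=v)


# ---------------------------------------------------------------------------
# log-likelihood and analytic score in packed coordinates


def _loglik_and_score(spec: FamilySpec, theta, y, X, Z, w):
    """Total weighted log-likelihood and its gradient w.r.t. packed theta."""
    fam = spec.family
    _, k_beta, k_gamma = _param_layout(spec)
    beta = theta[:k_beta]
    eta_c = np.clip(X @ beta, -500, 500)
    mu = np.exp(eta_c)
    psi = None
    if k_gamma:
        gamma = theta[k_beta:k_beta + k_gamma]
        eta_z = np.clip(Z @ gamma, -500, 500)
        psi = np.clip(expit(eta_z), 1e-12, 1 - 1e-12)
    v = float(np.exp(theta[-1])) if fam.has_dispersion else None
    r = 1.0 / v if v is not None else None

    per = logpmf(fam, y, mu, psi, v)
    ll = float(np.sum(w * per))

    is0 = y == 0
    a = np.zeros_like(mu)      # d ll_i / d eta_c,i
    d = None                   # d ll_i / d eta_z,i
    g_r = None                 # d ll_i / d r

    if fam is Family.POISSON:
        a = y - mu
    elif fam is Family.NB:
        a = (y - mu) * r / (r + mu)
        g_r = digamma(y + r) - digamma(r) + np.log(r / (r + mu)) + (mu - y) / (r + mu)
    else:
        log_psi = np.log(psi)
        log_1mpsi = np.log1p(-psi)
        if fam is Family.ZIP:
            la = np.logaddexp(log_psi, log_1mpsi - mu)
            a = np.where(is0, -np.exp(log_1mpsi - mu + np.log(mu) - la), y - mu)
            d = np.where(is0,
                         np.exp(log_psi + log_1mpsi + _log1mexp(-mu) - la),
                         -psi)
        elif fam is Family.ZINB:
            lp0 = _nb_logp0(mu, v)
            la = np.logaddexp(log_psi, log_1mpsi + lp0)
            w0 = np.exp(log_1mpsi + lp0 - la)          # (1-psi) p0 / A
            a = np.where(is0, -w0 * r * mu / (r + mu),
                         (y - mu) * r / (r + mu))
            d = np.where(is0, np.exp(log_psi + log_1mpsi + _log1mexp(lp0) - la),
                         -psi)
            dp0dr_over_p0 = np.log(r / (r + mu)) + mu / (r + mu)
            g_r_pos = (digamma(y + r) - digamma(r) + np.log(r / (r + mu))
                       + (mu - y) / (r + mu))
            g_r = np.where(is0, w0 * dp0dr_over_p0, g_r_pos)
        elif fam is Family.HP:
            d = np.where(is0, 1 - psi, -psi)
            with np.errstate(over="ignore"):
                ratio = np.exp(-mu - _log1mexp(-mu))   # e^-mu / (1 - e^-mu)
            a = np.where(is0, 0.0, y - mu - mu * ratio)
        elif fam is Family.HNB:
            d = np.where(is0, 1 - psi, -psi)
            lp0 = _nb_logp0(mu, v)
            p0_ratio = np.exp(lp0 - _log1mexp(lp0))    # p0 / (1 - p0)
            a = np.where(is0, 0.0,
                         r / (r + mu) * ((y - mu) - mu * p0_ratio))
            dp0dr_over_p0 = np.log(r / (r + mu)) + mu / (r + mu)
            g_r_pos = (digamma(y + r) - digamma(r) + np.log(r / (r + mu))
                       + (mu - y) / (r + mu) + p0_ratio * dp0dr_over_p0)
            g_r = np.where(is0, 0.0, g_r_pos)

    parts = [X.T @ (w * a)]
    if d is not None:
        parts.append(Z.T @ (w * d))
    if fam.has_dispersion:
        # chain rule: d/d log(v) = dr/dlog(v) * d/dr = -r * d/dr
        parts.append(np.array([np.sum(w * g_r) * (-r)]))
    score = np.concatenate(parts)
    return ll, score, per


def _numeric_hessian(fun_score, theta, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of an analytic score -> Hessian."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        h = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (fun_score(tp) - fun_score(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def fit(spec: FamilySpec, cohort: pd.DataFrame, outcome: str,
        options: FitOptions | None = None,
        weights: np.ndarray | None = None,
        start: ParameterSet | None = None) -> FitResult:
    """Maximize the family's log-likelihood over ``cohort[outcome]``.

    Runs BFGS from :func:`starting_values` plus ``n_starts - 1`` jittered
    starts and keeps the best optimum.  Likelihoods are unweighted unless
    ``weights`` is given (sampling weights are conventionally applied to
    descriptive statistics only).
    """
    options = options or FitOptions()
    y = cohort[outcome].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("outcome must contain non-negative integer counts")
    n = len(y)
    X = design_matrix(cohort, spec.count_design)
    Z = design_matrix(cohort, spec.zero_design) \
        if spec.family.has_zero_component else None
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    wsum = float(w.sum())

    theta0 = _pack(spec, start if start is not None
                   else starting_values(spec, cohort, outcome,
                                        weights=None if weights is None else w))

    def nll_grad(theta):
        ll, score, _ = _loglik_and_score(spec, theta, y, X, Z, w)
        return -ll / wsum, -score / wsum

    rng = np.random.default_rng(options.seed)
    starts = [theta0]
    for _ in range(options.n_starts - 1):
        starts.append(theta0 + rng.normal(size=theta0.size)
                      * options.jitter_scale * (1.0 + np.abs(theta0)))

    best = None
    n_converged = 0
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(nll_grad, s, jac=True, method="BFGS",
                           options={"gtol": options.gradient_tol / 10,
                                    "maxiter": options.max_iter})
        gnorm = float(np.max(np.abs(res.jac)))
        ok = np.all(np.isfinite(res.x)) and gnorm < options.gradient_tol
        if ok:
            n_converged += 1
        if best is None or (-res.fun) > (-best[0].fun) + 1e-12:
            best = (res, gnorm)
    res, gnorm = best
    theta = res.x

    ll_total, score_total, per_obs = _loglik_and_score(spec, theta, y, X, Z, w)
    grad_norm = float(np.max(np.abs(score_total))) / wsum

    def score_only(t):
        return _loglik_and_score(spec, t, y, X, Z, w)[1]

    H = _numeric_hessian(score_only, theta)
    neg_def = False
    vcov = None
    try:
        np.linalg.cholesky(-H)
        neg_def = True
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        warnings.warn("Hessian is not negative definite at the optimum; "
                      "vcov unavailable", stacklevel=2)

    converged = bool(grad_norm < options.gradient_tol and neg_def
                     and np.all(np.isfinite(theta)))
    names, _, _ = _param_layout(spec)
    result = FitResult(
        spec=spec,
        params=_unpack(spec, theta),
        loglik=float(ll_total),
        per_obs_loglik=per_obs,
        vcov=vcov,
        gradient_norm=grad_norm,
        hessian_neg_definite=neg_def,
        converged=converged,
        n_obs=n,
        n_params=len(theta),
        theta=theta,
        param_names=names,
        n_starts_converged=n_converged,
    )
    if not converged and n_converged == 0:
        warnings.warn(
            f"{spec.family.value} fit did not meet convergence criteria "
            f"(gradient max-norm {grad_norm:.3g}, "
            f"Hessian negative definite: {neg_def})", stacklevel=2,
        )
    return result


def effect_table(fit_result: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Rate ratios (count component) and odds ratios (binary component)
    with Wald confidence intervals.

    Binary-component coefficients are negated before exponentiating so the
    odds ratios describe the odds of *at least one visit*; a ratio below 1
    therefore means lower odds of any utilization.
    """
    if fit_result.vcov is None:
        raise ValueError("fit has no covariance matrix (Hessian not "
                         "negative definite); effect table unavailable")
    z = norm.ppf(0.5 + level / 2)
    se = np.sqrt(np.clip(np.diag(fit_result.vcov), 0, None))
    rows = []
    for j, name in enumerate(fit_result.param_names):
        component, _, term = name.partition(":")
        if component == "log_v":
            continue
        est = fit_result.theta[j]
        if component == "binary":
            est = -est  # orient toward odds of >=1 visit
        ratio = np.exp(est)
        lo, hi = np.exp(est - z * se[j]), np.exp(est + z * se[j])
        p = 2 * norm.sf(abs(est) / se[j]) if se[j] > 0 else np.nan
        rows.append({
            "term": term or name,
            "component": "count" if component == "count" else "binary",
            "estimate": est,
            "se": se[j],
            "ratio": ratio,
            "ci_low": lo,
            "ci_high": hi,
            "p_value": p,
            "is_reference": False,
        })
    return pd.DataFrame(rows)
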