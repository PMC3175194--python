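"""Count-data model families: densities, links, log-likelihoods and moments.

Six families are supported for modeling non-negative integer outcomes such
as per-person emergency-department visit counts:

``poisson``
    :math:`P(Y=y) = e^{-\\mu}\\mu^y / y!` with log link
    :math:`\\mu_i = e^{x_i\\beta}`.
``nb``
    Negative binomial (NB2): a Poisson model whose rate carries
    gamma-distributed unobserved heterogeneity, giving
    :math:`\\mathrm{Var}(Y) = \\mu + v\\mu^2` where ``v > 0`` is the
    dispersion parameter.
``zip`` / ``zinb``
    Zero-inflated mixtures: with probability :math:`\\psi_i` an observation
    belongs to a never-user class (a *structural* zero); with probability
    :math:`1-\\psi_i` it is drawn from the Poisson/NB count density (which
    contributes its own *sampling* zeros).
``hp`` / ``hnb``
    Hurdle models: :math:`\\psi_i` is the total probability of a zero count,
    and positive counts follow the zero-truncated Poisson/NB density with
    normalizers :math:`1-e^{-\\mu}` and :math:`1-(1+v\\mu)^{-1/v}`.

In all mixture/hurdle families the zero component is parameterized through
a logistic regression, :math:`\\psi_i = \\mathrm{expit}(z_i\\gamma)`, where
the covariate set :math:`z_i` need not equal the count-component set
:math:`x_i`.  Note that :math:`\\psi` is oriented toward the *zero* state;
the reporting layer in :mod:`edcounts.estimate` flips the sign of the
binary-component coefficients so published odds ratios describe the odds of
at least one visit.

All functions are vectorized over observations and compute in log space
(log-gamma, log-sum-exp) so they remain finite for counts up to ~1e6 and
means up to ~1e4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, xlogy

__all__ = [
    "Family",
    "FamilySpec",
    "ParameterSet",
    "LinkedPredictors",
    "MomentPair",
    "link_predictors",
    "logpmf",
    "conditional_moments",
    "total_loglik",
    "CANONICAL_ORDER",
]


class Family(str, Enum):
    """The six count-model families, in their canonical comparison order."""

    POISSON = "poisson"
    NB = "nb"
    ZIP = "zip"
    ZINB = "zinb"
    HP = "hp"
    HNB = "hnb"

    @property
    def has_zero_component(self) -> bool:
        return self in _ZERO_COMPONENT

    @property
    def has_dispersion(self) -> bool:
        return self in _DISPERSED

    @property
    def is_hurdle(self) -> bool:
        return self in _HURDLE

    @property
    def is_zero_inflated(self) -> bool:
        return self in _ZERO_INFLATED


_ZERO_INFLATED = frozenset({Family.ZIP, Family.ZINB})
_HURDLE = frozenset({Family.HP, Family.HNB})
_ZERO_COMPONENT = _ZERO_INFLATED | _HURDLE
_DISPERSED = frozenset({Family.NB, Family.ZINB, Family.HNB})

#: Display/tie-break ordering used in comparison matrices.
CANONICAL_ORDER = [Family.POISSON, Family.NB, Family.ZIP, Family.ZINB,
                   Family.HP, Family.HNB]

# Probabilities are floored here before logging so optimizer excursions into
# pathological corners yield large-but-finite penalties instead of -inf.
_LOG_FLOOR = -745.0
_PSI_EPS = 1e-12
_ETA_CLIP = 700.0


def _as_family(family) -> Family:
    return family if isinstance(family, Family) else Family(str(family).lower())


@dataclass(frozen=True)
class FamilySpec:
    """A family together with the covariate terms of each component.

    ``count_design``/``zero_design`` list numeric design-matrix columns
    (typically treatment-coded dummies); an intercept column of ones is
    always prepended implicitly and must not be listed.
    """

    family: Family
    count_design: tuple = ()
    zero_design: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "family", _as_family(self.family))
        object.__setattr__(self, "count_design", tuple(self.count_design))
        object.__setattr__(self, "zero_design", tuple(self.zero_design))
        if self.family.has_zero_component:
            pass  # empty zero_design means intercept-only hurdle/inflation
        elif self.zero_design:
            raise ValueError(
                f"{self.family.value} has no zero component; zero_design must be empty"
            )

    @property
    def n_params(self) -> int:
        k = 1 + len(self.count_design)
        if self.family.has_zero_component:
            k += 1 + len(self.zero_design)
        if self.family.has_dispersion:
            k += 1
        return k


@dataclass
class ParameterSet:
    """Coefficients for one family: count-component ``beta`` (intercept
    first), zero-component ``gamma`` (intercept first; ``None`` for
    poisson/nb) and NB dispersion ``v`` (``None`` where not applicable)."""

    beta: np.ndarray
    gamma: np.ndarray | None = None
    v: float | None = None

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.gamma is not None:
            self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.v is not None:
            self.v = float(self.v)
            if not self.v > 0:
                raise ValueError("dispersion v must be > 0")

    def validate_against(self, spec: FamilySpec) -> None:
        if len(self.beta) != 1 + len(spec.count_design):
            raise ValueError(
                f"beta has length {len(self.beta)}, expected "
                f"{1 + len(spec.count_design)} (intercept + count_design)"
            )
        if spec.family.has_zero_component:
            if self.gamma is None:
                raise ValueError(f"{spec.family.value} requires gamma")
            if len(self.gamma) != 1 + len(spec.zero_design):
                raise ValueError(
                    f"gamma has length {len(self.gamma)}, expected "
                    f"{1 + len(spec.zero_design)} (intercept + zero_design)"
                )
        if spec.family.has_dispersion and self.v is None:
            raise ValueError(f"{spec.family.value} requires dispersion v")


@dataclass
class LinkedPredictors:
    """Per-observation linked quantities: mean ``mu``, zero-component
    probability ``psi`` (``None`` without a zero component) and its linear
    predictor ``eta``."""

    mu: np.ndarray
    psi: np.ndarray | None = None
    eta: np.ndarray | None = None
    clipped: bool = False


@dataclass
class MomentPair:
    mean: np.ndarray
    variance: np.ndarray


def design_matrix(cohort: pd.DataFrame, terms) -> np.ndarray:
    """Stack an intercept column with the named numeric columns of ``cohort``."""
    n = len(cohort)
    cols = [np.ones(n)]
    for t in terms:
        if t not in cohort.columns:
            raise KeyError(f"design term {t!r} not found in cohort columns")
        cols.append(cohort[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def link_predictors(spec: FamilySpec, params: ParameterSet,
                    cohort: pd.DataFrame) -> LinkedPredictors:
    """Map coefficients to per-row ``mu`` (log link) and ``psi`` (logit link)."""
    params.validate_against(spec)
    X = design_matrix(cohort, spec.count_design)
    eta_count = X @ params.beta
    clipped = bool(np.any(np.abs(eta_count) > _ETA_CLIP))
    mu = np.exp(np.clip(eta_count, -_ETA_CLIP, _ETA_CLIP))
    psi = eta = None
    if spec.family.has_zero_component:
        Z = design_matrix(cohort, spec.zero_design)
        eta = Z @ params.gamma
        psi = np.clip(expit(eta), _PSI_EPS, 1.0 - _PSI_EPS)
    return LinkedPredictors(mu=mu, psi=psi, eta=eta, clipped=clipped)


# ---------------------------------------------------------------------------
# log-densities


def _log1mexp(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(x)) for x < 0, stable near both 0 and -inf."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x > -0.6931471805599453  # ln 2
    with np.errstate(divide="ignore"):
        out[small] = np.log(-np.expm1(x[small]))
        out[~small] = np.log1p(-np.exp(x[~small]))
    return out


def _pois_logpmf(y, mu):
    return xlogy(y, mu) - mu - gammaln(y + 1.0)


def _nb_logpmf(y, mu, v):
    r = 1.0 / v
    log1pvmu = np.log1p(v * mu)
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            - r * log1pvmu + xlogy(y, v * mu) - y * log1pvmu)


def _nb_logp0(mu, v):
    # log P(Y=0) = -(1/v) log(1 + v mu)
    return -np.log1p(v * mu) / v


def _validate_y(y):
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.number):
        raise TypeError("counts must be numeric")
    yf = y.astype(float)
    if np.any(yf < 0) or np.any(yf != np.floor(yf)):
        raise ValueError("counts must be non-negative integers")
    return yf


def _check_domain(family: Family, mu, psi, v):
    mu = np.asarray(mu, dtype=float)
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
        raise ValueError("mu must be finite and > 0")
    if family.has_zero_component:
        if psi is None:
            raise ValueError(f"{family.value} requires psi")
        psi = np.clip(np.asarray(psi, dtype=float), _PSI_EPS, 1 - _PSI_EPS)
    if family.has_dispersion:
        if v is None or not np.all(np.asarray(v) > 0):
            raise ValueError(f"{family.value} requires dispersion v > 0")
    return mu, psi, v


def logpmf(family, y, mu, psi=None, v=None) -> np.ndarray:
    """Log probability mass of ``y`` under the given family.

    Parameters follow the linked scale: ``mu`` is the count-component mean,
    ``psi`` the zero-component probability (structural-zero probability for
    zip/zinb, total zero probability for hp/hnb), ``v`` the NB dispersion.
    """
    family = _as_family(family)
    y = _validate_y(y)
    mu, psi, v = _check_domain(family, mu, psi, v)
    y, mu = np.broadcast_arrays(y, mu)
    y = y.astype(float)

    if family is Family.POISSON:
        return _pois_logpmf(y, mu)
    if family is Family.NB:
        return _nb_logpmf(y, mu, v)

    psi = np.broadcast_to(psi, y.shape)
    log_psi = np.log(psi)
    log_1mpsi = np.log1p(-psi)
    is0 = y == 0

    if family is Family.ZIP:
        zero = np.logaddexp(log_psi, log_1mpsi - mu)
        pos = log_1mpsi + _pois_logpmf(y, mu)
    elif family is Family.ZINB:
        zero = np.logaddexp(log_psi, log_1mpsi + _nb_logp0(mu, v))
        pos = log_1mpsi + _nb_logpmf(y, mu, v)
    elif family is Family.HP:
        zero = log_psi
        pos = log_1mpsi + _pois_logpmf(y, mu) - _log1mexp(-mu)
    elif family is Family.HNB:
        zero = log_psi
        pos = log_1mpsi + _nb_logpmf(y, mu, v) - _log1mexp(_nb_logp0(mu, v))
    else:  # pragma: no cover
        raise ValueError(family)
    out = np.where(is0, zero, pos)
    return np.maximum(out, _LOG_FLOOR)


def conditional_moments(family, mu, psi=None, v=None) -> MomentPair:
    """Closed-form conditional mean and variance of each family.

    Poisson: (mu, mu).  NB: (mu, mu(1+v*mu)).  ZIP: (mu(1-psi),
    mu(1-psi)(1+mu*psi)).  ZINB: (mu(1-psi), mu(1-psi)(1+mu(psi+v))).
    Hurdle moments come from the zero-truncated density's first two moments
    combined with the Bernoulli hurdle via the law of total variance.
    """
    family = _as_family(family)
    mu, psi, v = _check_domain(family, mu, psi, v)
    mu = np.asarray(mu, dtype=float)

    if family is Family.POISSON:
        return MomentPair(mu, mu.copy())
    if family is Family.NB:
        return MomentPair(mu, mu * (1.0 + v * mu))
    if family is Family.ZIP:
        mean = mu * (1 - psi)
        return MomentPair(mean, mean * (1.0 + mu * psi))
    if family is Family.ZINB:
        mean = mu * (1 - psi)
        return MomentPair(mean, mean * (1.0 + mu * (psi + v)))
    # hurdle families: E[Y] = (1-psi) E[Y|Y>0], E[Y^2] = (1-psi) E[Y^2|Y>0]
    if family is Family.HP:
        p0 = np.exp(-mu)
        ey2_full = mu + mu ** 2
    else:  # HNB
        p0 = np.exp(_nb_logp0(mu, v))
        ey2_full = mu + (1.0 + v) * mu ** 2
    trunc_mean = mu / (1.0 - p0)
    trunc_ey2 = ey2_full / (1.0 - p0)
    mean = (1 - psi) * trunc_mean
    var = (1 - psi) * trunc_ey2 - mean ** 2
    return MomentPair(mean, var)


def total_loglik(spec: FamilySpec, params: ParameterSet, cohort: pd.DataFrame,
                 outcome: str, weights: np.ndarray | None = None):
    """Total and per-observation log-likelihood of ``cohort[outcome]``.

    Returns ``(total, per_obs)``; ``total = sum(w_i * per_obs_i)`` (weights
    default to 1).  Raises if any per-observation term is non-finite,
    naming the offending row.
    """
    if outcome not in cohort.columns:
        raise KeyError(f"outcome column {outcome!r} not in cohort")
    y = _validate_y(cohort[outcome].to_numpy())
    linked = link_predictors(spec, params, cohort)
    per_obs = logpmf(spec.family, y, linked.mu, linked.psi, params.v)
    if not np.all(np.isfinite(per_obs)):
        bad = int(np.flatnonzero(~np.isfinite(per_obs))[0])
        raise FloatingPointError(
            f"non-finite log-likelihood at row {bad} "
            f"(y={y[bad]}, mu={linked.mu[bad]})"
        )
    if weights is None:
        total = float(per_obs.sum())
    else:
        weights = np.asarray(weights, dtype=float)
        total = float(np.sum(weights * per_obs))
    return total, per_obs
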