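import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from edcounts.families import Family, FamilySpec, ParameterSet
from edcounts.simulate import simulate_outcomes


def family_testpoints(rng, family, k=10):
    """Randomized in-domain (mu, psi, v) triples for one family."""
    pts = []
    for _ in range(k):
        mu = float(rng.uniform(0.1, 15.0))
        v = float(rng.uniform(0.05, 2.5)) if Family(family).has_dispersion else None
        psi = float(rng.uniform(0.05, 0.95)) \
            if Family(family).has_zero_component else None
        pts.append((mu, psi, v))
    return pts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210915)


@pytest.fixture(scope="session")
def small_cohort():
    """200-row coded cohort with one continuous and one binary covariate
    plus Poisson and NB outcomes simulated from known truth."""
    rng = np.random.default_rng(42)
    n = 200
    df = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.integers(0, 2, n).astype(float),
    })
    pois_spec = FamilySpec(Family.POISSON, count_design=("x1", "x2"))
    df["y_pois"] = simulate_outcomes(
        df, pois_spec, ParameterSet(beta=[0.3, 0.4, -0.5]), seed=7)
    nb_spec = FamilySpec(Family.NB, count_design=("x1", "x2"))
    df["y_nb"] = simulate_outcomes(
        df, nb_spec, ParameterSet(beta=[0.5, 0.4, -0.5], v=0.8), seed=8)
    return df
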