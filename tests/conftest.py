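import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_pedigree():
    from glucometab.pedigree import generate_pedigree

    return generate_pedigree(6, (8, 12), seed=11)


@pytest.fixture(scope="session")
def family_cohort():
    """Moderate cohort with family structure shared across association tests."""
    from glucometab.pedigree import generate_pedigree
    from glucometab.simulate import CohortConfig, generate_cohort

    ped = generate_pedigree(30, (10, 16), seed=5)
    cohort = generate_cohort(ped, CohortConfig(seed=7))
    return ped, cohort


def make_null_problem(n=300, p=40, seed=0, beta=None, noise=1.0):
    """Standardized design + response for elastic-net and LMM tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    b = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    y = X @ b + noise * rng.normal(size=n)
    return X, y
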