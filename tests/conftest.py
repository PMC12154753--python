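import numpy as np
import pytest

from spirolms.cohort import CohortSpec, generate_cohort
from spirolms.distributions import BCCGParams
from spirolms.equations import load_ise


@pytest.fixture(scope="session")
def ise():
    """Packaged equation pair {'male': EquationSet, 'female': EquationSet}."""
    return load_ise()


@pytest.fixture(scope="session")
def male_fvc_params():
    """Subject-specific male FVC parameters at the cohort median demographics."""
    eq = load_ise("male")
    model = eq["fvc"]
    return BCCGParams(
        float(model.mu(174.0, 28.57)),
        float(model.sigma(174.0, 28.57)),
        float(model.nu(174.0, 28.57)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-subject truth-generated cohort shared across read-only tests."""
    return generate_cohort(CohortSpec(n=2000, seed=11))


def single_sex_cohort(sex: str, n: int, seed: int):
    """Cohort of n subjects of one sex (generator requires both sexes present)."""
    frac = 1.0 / (n + 1) if sex == "male" else n / (n + 1)
    df = generate_cohort(CohortSpec(n=n + 1, female_fraction=frac, seed=seed))
    return df[df["sex"] == sex]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
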