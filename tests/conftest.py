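import numpy as np
import pytest

from qmriskin.classify import SVMConfig
from qmriskin.cohort import CohortSpec, draw_cohort


@pytest.fixture(scope="session")
def cohort_table():
    """Default 9+9 synthetic cohort (km halved, T2 +30% in the OI group)."""
    return draw_cohort(CohortSpec(), seed=20160714)


@pytest.fixture(scope="session")
def separated_table():
    """Two groups separated by many SDs on every parameter."""
    spec = CohortSpec(
        control_means={"MTR": 0.3, "km": 1.0, "T2": 20.0, "T1": 0.8,
                       "ADC": 0.5e-3},
        control_sds={"MTR": 0.01, "km": 0.05, "T2": 0.5, "T1": 0.02,
                     "ADC": 1e-5},
        oi_means={"MTR": 0.7, "km": 3.0, "T2": 60.0, "T1": 2.0,
                  "ADC": 1.5e-3},
        oi_sds={"MTR": 0.01, "km": 0.05, "T2": 0.5, "T1": 0.02, "ADC": 1e-5},
    )
    return draw_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def null_spec():
    """Identical group distributions: no class signal at all."""
    means = {"MTR": 0.5, "km": 2.0, "T2": 30.0, "T1": 1.2, "ADC": 1e-3}
    sds = {"MTR": 0.05, "km": 0.3, "T2": 3.0, "T1": 0.1, "ADC": 1e-4}
    return CohortSpec(control_means=means, control_sds=sds,
                      oi_means=dict(means), oi_sds=dict(sds))


@pytest.fixture(scope="session")
def fast_svm():
    """Coarse 3x3 hyperparameter grid for runtime-sensitive tests."""
    return SVMConfig(n_grid=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
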