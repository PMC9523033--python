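import numpy as np
import pytest

from decliner import CohortSpec, PlantedEffect, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort exercising every encoding branch."""
    spec = CohortSpec(
        n_samples=60,
        rapid_fraction=0.2,
        n_plasma_metab=6,
        n_urine_metab=6,
        n_clinical=8,
        missing_rate_type1=0.2,
        missing_rate_type2=0.05,
        seed=11,
    )
    cohort, egfr, truth = generate_cohort(spec)
    return cohort, egfr, truth


@pytest.fixture(scope="session")
def rapid_y(small_cohort):
    _, _, truth = small_cohort
    return truth.rapid.astype(int)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
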