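import numpy as np
import pytest

import radpoc as rp


@pytest.fixture(scope="session")
def model_set():
    return rp.example_model_set()


@pytest.fixture(scope="session")
def population():
    return rp.generate_population_table(np.random.default_rng(42))


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def simple_case():
    return rp.CaseSpec(
        cancer_group="DIG",
        sex="m",
        birth_year=1950,
        diagnosis_year=2010,
        exposures=[rp.ExposureEvent(1980, {"type": "fixed", "value": 500.0})],
    )


@pytest.fixture
def frozen_config():
    """Everything frozen: the run collapses onto the closed-form value."""
    return rp.RunConfig(
        iterations=50,
        transfer_mode="fixed",
        transfer_value=0.5,
        sample_parameters=False,
        sample_latency=False,
        dref_enabled=False,
        sample_baseline=False,
        sample_doses=False,
        sample_cohort_factors=False,
        sample_generic_b=False,
    )
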