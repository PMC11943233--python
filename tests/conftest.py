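import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from nmbsim import (
    apply_covariates,
    default_params,
    reference_patient,
    run_pipeline,
    simulate_patient,
)

#: cohort seed used by the end-to-end suite (any small integer works; the
#: cohort-level assertions use wide stochastic tolerances)
COHORT_SEED = 1


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def ref_patient():
    return reference_patient()


@pytest.fixture(scope="session")
def ref_params(params, ref_patient):
    return apply_covariates(params, ref_patient)


@pytest.fixture(scope="session")
def ref_protocol(ref_patient, ref_params):
    """Full protocol run for the reference adult (2.5 h operation)."""
    return simulate_patient(ref_patient, ref_params, operation_time_h=2.5)


@pytest.fixture(scope="session")
def cohort_run():
    """End-to-end synthetic cohort at the clinical-series size (n = 74)."""
    return run_pipeline(n=74, seed=COHORT_SEED)
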