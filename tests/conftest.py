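import numpy as np
import pytest

from meronat import (CohortSpec, DosingRegimen, Patient, PopPKModel,
                     RegressionRiskModel, load_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20210468)


@pytest.fixture
def pk_model():
    return PopPKModel()


@pytest.fixture
def pk_model_novar():
    """Deterministic PK model: no IIV, no residual error."""
    return PopPKModel(omega={"cl": 0.0, "v1": 0.0, "q": 0.0, "v2": 0.0},
                      residual_prop_sd=0.0, residual_add_sd=0.0)


@pytest.fixture
def regimen():
    return DosingRegimen()


@pytest.fixture
def median_patient():
    """A patient at the cohort median characteristics."""
    return Patient(id="median", sex="male", age=57.0, weight=73.0,
                   serum_creatinine=1.0, serum_albumin=2.5, clcr=86.4)


def make_patient(clcr, pid=None, **kwargs):
    defaults = dict(sex="male", age=57.0, weight=73.0, serum_albumin=2.5)
    defaults.update(kwargs)
    return Patient(id=pid or f"p{clcr:g}", clcr=clcr, **defaults)


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture
def reg_model():
    """A hand-set regression model with known, convenient coefficients."""
    return RegressionRiskModel(intercept=9.5, slope=-2.0, residual_sd=0.6,
                               n_train=200, mean_ln_x=4.45, sxx=60.0)


@pytest.fixture
def default_config():
    return load_config()


@pytest.fixture
def cohort_spec():
    return CohortSpec()
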