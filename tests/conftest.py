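import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rivaddi import (DDIModel, ExposureWindow, InductionParams, Patient,
                     RifampinParams, RivaroxabanParams)

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def induction_params():
    """Published induction constants (CYP3A4 turnover, rifampin partitioning)."""
    return InductionParams()


@pytest.fixture(scope="session")
def model():
    """Default coupled model: reference patient (60.3 kg, CrCl 118 ml/min)."""
    return DDIModel()


@pytest.fixture(scope="session")
def frozen_model():
    """Model with induction switched off (negligible Emax): two independent
    linear one-compartment systems, matched by the Bateman closed form."""
    return DDIModel(induction=InductionParams(emax=1e-12))


@pytest.fixture(scope="session")
def median_patient_model():
    """Reference-renal-function patient (CrCl = crcl_ref): renal scalar 1."""
    return DDIModel(patient=Patient(age=64.0, weight=63.5, sex="male", crcl=104.0))


@pytest.fixture(scope="session")
def window():
    return ExposureWindow()


def bateman(t, dose_mg, ka, v_l, cl):
    """Closed-form one-compartment concentration after an oral bolus (mg/L)."""
    ke = cl / v_l
    t = np.asarray(t, dtype=float)
    return dose_mg * ka / (v_l * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
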