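"""Rivaroxaban disposition with pathway-partitioned clearance.

The victim drug is described by a reduced one-compartment model with
first-order absorption whose apparent total clearance is split into four
elimination routes: hepatic CYP3A4 metabolism, hepatic non-CYP3A4
elimination (hydrolysis and other CYPs), renal glomerular filtration and
renal P-gp-mediated tubular secretion.  The CYP3A4 and P-gp routes scale
with the induced enzyme activities; the two renal routes additionally
scale linearly with the patient's creatinine clearance relative to a
reference value.

Default pathway fractions are calibration choices: they place uninduced
10 mg qd steady-state exposure mid-way through the published reference
window and give a steady-state induced/baseline clearance ratio of about
three under rifampin 600 mg qd, consistent with a tripled daily dose
restoring in-window exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

from .induction import EnzymeState

__all__ = ["RivaroxabanParams", "Patient", "induced_total_clearance", "rivaroxaban_rhs"]

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class RivaroxabanParams:
    """Apparent oral disposition parameters of rivaroxaban.

    ``ka`` absorption rate constant (1/h); ``v`` apparent central volume
    (L); ``cl_total`` apparent total clearance at baseline (L/h);
    ``f_cyp3a4``, ``f_hep_other``, ``f_pgp``, ``f_gfr`` pathway fractions
    of ``cl_total`` (must sum to one); ``crcl_ref`` reference creatinine
    clearance (ml/min) at which the renal pathways take their nominal
    share.
    """

    ka: float = 1.4
    v: float = 50.0
    cl_total: float = 10.0
    f_cyp3a4: float = 0.18
    f_hep_other: float = 0.46
    f_pgp: float = 0.30
    f_gfr: float = 0.06
    crcl_ref: float = 104.0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.v <= 0 or self.cl_total <= 0 or self.crcl_ref <= 0:
            raise ValueError("rates, volume, clearance and crcl_ref must be positive")
        fracs = (self.f_cyp3a4, self.f_hep_other, self.f_pgp, self.f_gfr)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError(f"pathway fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > _FRACTION_TOL:
            raise ValueError(
                f"pathway fractions must sum to 1 within {_FRACTION_TOL}, got {sum(fracs)}")


@dataclass(frozen=True)
class Patient:
    """Individual covariates used by the model.

    ``weight`` (kg) sizes the rifampin distribution volume; ``crcl``
    (ml/min) scales the renal elimination routes of rivaroxaban.
    """

    age: float = 64.0
    weight: float = 60.3
    sex: str = "male"
    crcl: float = 118.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.crcl <= 0:
            raise ValueError(f"creatinine clearance must be positive, got {self.crcl}")


def induced_total_clearance(params: RivaroxabanParams, enz: EnzymeState,
                            patient: Patient) -> float:
    """Instantaneous apparent total clearance of rivaroxaban (L/h).

    CL(t) = CL_total * [f_cyp*Et_liver + f_hep_other
                        + r * (f_pgp*Et_renal + f_gfr)]

    with ``r = crcl / crcl_ref`` the renal-function scalar.  Returns the
    baseline ``cl_total`` when both activities are 1 and ``r = 1``.
    """
    if enz.et_liver <= 0 or enz.et_renal <= 0:
        raise ValueError("enzyme activities must be positive")
    r = patient.crcl / params.crcl_ref
    return params.cl_total * (
        params.f_cyp3a4 * enz.et_liver
        + params.f_hep_other
        + r * (params.f_pgp * enz.et_renal + params.f_gfr)
    )


def rivaroxaban_rhs(a_gut: float, c_central: float, enz: EnzymeState,
                    params: RivaroxabanParams, patient: Patient) -> tuple[float, float]:
    """Time derivatives ``(dA_gut/dt, dC/dt)`` of the rivaroxaban system.

    Amounts in mg, central concentration in mg/L (multiply by 1000 for
    the conventional ng/ml reporting scale).
    """
    if a_gut < 0 or c_central < 0:
        raise ValueError("rivaroxaban state must be non-negative")
    cl = induced_total_clearance(params, enz, patient)
    da = -params.ka * a_gut
    dc = params.ka * a_gut / params.v - (cl / params.v) * c_central
    return da, dc
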