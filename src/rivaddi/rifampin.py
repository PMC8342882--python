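"""One-compartment rifampin pharmacokinetics with self-induction.

Rifampin is modeled as a one-compartment system with first-order oral
absorption and first-order elimination.  Its total clearance is not
constant: the CYP3A4 fraction of hepatic clearance scales with the
hepatic enzyme activity that rifampin itself induces, so repeated dosing
lowers rifampin exposure over the first one to two weeks
(autoinduction).  Parameters are apparent oral values — bioavailability
is absorbed into clearance and volume.
"""

from __future__ import annotations

from dataclasses import dataclass

from .induction import InductionParams, rifampin_total_clearance

__all__ = [
    "RifampinParams",
    "RifampinState",
    "rifampin_rhs",
    "liver_site_concentration",
    "renal_site_concentration",
]


@dataclass(frozen=True)
class RifampinParams:
    """Rifampin disposition parameters (apparent oral).

    ``ka`` first-order absorption rate constant (1/h); ``v_per_kg``
    volume of distribution per body weight (L/kg); ``cl_t`` total
    clearance of a single (uninduced) dose (L/h); ``cl_r`` renal
    clearance (L/h); ``fm_cyp3a4`` fraction of hepatic intrinsic
    clearance mediated by CYP3A4, the part subject to self-induction.
    """

    ka: float = 0.58
    v_per_kg: float = 0.33
    cl_t: float = 7.4
    cl_r: float = 1.5
    fm_cyp3a4: float = 0.2

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.v_per_kg <= 0:
            raise ValueError("ka and v_per_kg must be positive")
        if self.cl_t <= 0 or self.cl_r < 0:
            raise ValueError("clearances must be positive (cl_r >= 0)")
        if self.cl_r > self.cl_t:
            raise ValueError(
                f"renal clearance {self.cl_r} exceeds total clearance {self.cl_t}")
        if not 0 <= self.fm_cyp3a4 <= 1:
            raise ValueError(f"fm_cyp3a4 must lie in [0, 1], got {self.fm_cyp3a4}")


@dataclass
class RifampinState:
    """Amount in the absorption depot (mg) and plasma concentration (mg/L)."""

    a_gut: float = 0.0
    c_plasma: float = 0.0


def rifampin_rhs(state: RifampinState, et_liver: float, params: RifampinParams,
                 body_weight: float) -> tuple[float, float]:
    """Time derivatives ``(dA_gut/dt, dC/dt)`` of the rifampin system.

    The depot empties with rate ``ka``; the central compartment receives
    the absorbed amount scaled by the distribution volume ``v_per_kg *
    body_weight`` and is cleared with the self-induced total clearance
    evaluated at the current hepatic activity.
    """
    if body_weight <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight}")
    if state.a_gut < 0 or state.c_plasma < 0:
        raise ValueError("rifampin state must be non-negative")
    v = params.v_per_kg * body_weight
    cl = rifampin_total_clearance(et_liver, params)
    da = -params.ka * state.a_gut
    dc = params.ka * state.a_gut / v - (cl / v) * state.c_plasma
    return da, dc


def liver_site_concentration(c_plasma: float, params: InductionParams) -> float:
    """Total hepatic inducer concentration in µM.

    Applies the liver partition coefficient to the plasma concentration
    (mg/L) and converts to µM with the inducer molar mass.  The unbound
    fraction is applied later, inside the induction rate equation.
    """
    if c_plasma < 0:
        raise ValueError(f"plasma concentration must be non-negative, got {c_plasma}")
    return params.kp_liver * c_plasma * 1000.0 / params.mw_inducer


def renal_site_concentration(c_plasma: float, params: InductionParams) -> float:
    """Renal-site inducer concentration in µM.

    No renal partition coefficient is available, so the plasma
    concentration itself is used (conservative default), converted to µM.
    """
    if c_plasma < 0:
        raise ValueError(f"plasma concentration must be non-negative, got {c_plasma}")
    return c_plasma * 1000.0 / params.mw_inducer
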