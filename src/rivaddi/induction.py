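"""Enzyme/transporter induction turnover kinetics.

Rifampin induces hepatic CYP3A4 and renal P-glycoprotein through a
turnover mechanism: enzyme synthesis is stimulated by the unbound inducer
concentration at the site through an Emax/EC50 relationship, while
degradation stays first order with rate constant ``kdeg``.  The relative
activity ``E(t)`` (fold of baseline) therefore relaxes toward

    E_ss = E0 * (1 + Emax * occ),   occ = fu*C / (EC50*fu_hep + fu*C)

with time constant ``1/kdeg`` (a half-life of about 72 h for CYP3A4),
which is what makes both the onset and the washout of the interaction
gradual rather than instantaneous.  The in-vitro EC50 is corrected by the
free fraction measured in the hepatocyte incubation (``fu_hep``); the
in-vivo drive uses the site-specific unbound fraction.

P-gp induction is assumed to follow the same parameters as CYP3A4 (both
are regulated by the pregnane xenobiotic receptor), evaluated at the
renal site concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "InductionParams",
    "EnzymeState",
    "enzyme_rate",
    "steady_state_activity",
    "induced_cl_cyp",
    "induced_cl_pgp",
    "rifampin_total_clearance",
]


@dataclass(frozen=True)
class InductionParams:
    """Turnover/induction constants for the perpetrator drug.

    Parameters
    ----------
    e0 : float
        Baseline relative enzyme activity (fold); 1 by definition.
    emax : float
        Maximal fold stimulation of enzyme synthesis (dimensionless).
    ec50_um : float
        Inducer concentration at half-maximal induction (µM), as measured
        in vitro.
    kdeg : float
        First-order enzyme degradation rate constant (1/h).
    fu_hep : float
        Free fraction of inducer in the hepatocyte incubation that
        produced ``ec50_um``; corrects EC50 to an unbound scale.
    kp_liver : float
        Liver-to-plasma partition coefficient of the inducer.
    fu_liver : float
        Unbound fraction of inducer in the liver.
    fu_renal_site : float
        Unbound fraction applied at the renal site.  Defaults to the
        hepatic value since no renal-specific measurement is available.
    mw_inducer : float
        Molar mass of the inducer (g/mol); bridges mass-based plasma
        concentrations (mg/L) to the molar EC50 scale (µM).
    """

    e0: float = 1.0
    emax: float = 9.0
    ec50_um: float = 0.8
    kdeg: float = 0.0096
    fu_hep: float = 0.42
    kp_liver: float = 0.27
    fu_liver: float = 0.609
    fu_renal_site: float = 0.609
    mw_inducer: float = 822.94

    def __post_init__(self) -> None:
        for name in ("e0", "emax", "ec50_um", "kdeg", "kp_liver", "mw_inducer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("fu_hep", "fu_liver", "fu_renal_site"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    def fu_site(self, site: str) -> float:
        if site == "liver":
            return self.fu_liver
        if site == "renal":
            return self.fu_renal_site
        raise ValueError(f"unknown site {site!r}; expected 'liver' or 'renal'")


@dataclass
class EnzymeState:
    """Relative activities of the two induced elimination routes.

    ``et_liver`` scales CYP3A4-mediated hepatic clearance, ``et_renal``
    scales P-gp-mediated tubular secretion.  Both are bounded between the
    baseline ``e0`` and the saturated ceiling ``e0 * (1 + emax)`` along
    any trajectory driven by non-negative inducer concentrations.
    """

    et_liver: float = 1.0
    et_renal: float = 1.0


def enzyme_rate(et: float, c_site_um: float, params: InductionParams,
                site: str = "liver") -> float:
    """Rate of change of relative enzyme activity (fold/h).

    Implements the turnover equation

        dE/dt = kdeg*E0*Emax * fu*C / (EC50*fu_hep + fu*C) + kdeg*(E0 - E)

    with ``fu`` the site-specific unbound fraction and ``C`` the total
    site concentration in µM.  At ``C = 0`` the baseline ``E = E0`` is a
    fixed point; at saturating ``C`` the fixed point is ``E0*(1+Emax)``.
    """
    if et <= 0:
        raise ValueError(f"enzyme activity must be positive, got {et}")
    if c_site_um < 0:
        raise ValueError(f"site concentration must be non-negative, got {c_site_um}")
    fu = params.fu_site(site)
    unbound = fu * c_site_um
    drive = unbound / (params.ec50_um * params.fu_hep + unbound) if unbound > 0 else 0.0
    return params.kdeg * params.e0 * params.emax * drive + params.kdeg * (params.e0 - et)


def steady_state_activity(c_site_um: float, params: InductionParams,
                          site: str = "liver") -> float:
    """Closed-form fixed point of :func:`enzyme_rate` at constant inducer.

    Returns ``E0 * (1 + Emax * occ)`` with the same occupancy term as the
    rate equation; ``enzyme_rate`` evaluated here is zero to machine
    precision.
    """
    if c_site_um < 0:
        raise ValueError(f"site concentration must be non-negative, got {c_site_um}")
    fu = params.fu_site(site)
    unbound = fu * c_site_um
    occ = unbound / (params.ec50_um * params.fu_hep + unbound) if unbound > 0 else 0.0
    return params.e0 * (1.0 + params.emax * occ)


def induced_cl_cyp(cl_cyp: float, et_liver: float) -> float:
    """CYP3A4-mediated clearance scaled by the hepatic activity (L/h)."""
    if cl_cyp < 0:
        raise ValueError(f"clearance must be non-negative, got {cl_cyp}")
    if et_liver <= 0:
        raise ValueError(f"enzyme activity must be positive, got {et_liver}")
    return cl_cyp * et_liver


def induced_cl_pgp(cl_tubular: float, et_renal: float) -> float:
    """P-gp-mediated tubular secretion scaled by the renal activity (L/h)."""
    if cl_tubular < 0:
        raise ValueError(f"clearance must be non-negative, got {cl_tubular}")
    if et_renal <= 0:
        raise ValueError(f"enzyme activity must be positive, got {et_renal}")
    return cl_tubular * et_renal


def rifampin_total_clearance(et_liver: float, rif) -> float:
    """Total rifampin clearance under self-induction (L/h).

    The hepatic part of the single-dose total clearance is split into a
    CYP3A4 fraction ``fm`` that scales with the induced activity and a
    residual fraction that does not:

        CL(E) = CL_R + fm*E*(CL_t - CL_R) + (1 - fm)*(CL_t - CL_R)

    so at baseline (``E = 1``) the uninduced total clearance ``CL_t`` is
    recovered exactly.

    Parameters
    ----------
    et_liver : float
        Relative hepatic CYP3A4 activity (fold).
    rif : RifampinParams
        Must expose ``cl_t``, ``cl_r`` and ``fm_cyp3a4``.
    """
    if rif.cl_r > rif.cl_t:
        raise ValueError(
            f"renal clearance {rif.cl_r} exceeds total clearance {rif.cl_t}")
    if et_liver <= 0:
        raise ValueError(f"enzyme activity must be positive, got {et_liver}")
    hepatic = rif.cl_t - rif.cl_r
    fm = rif.fm_cyp3a4
    return rif.cl_r + fm * et_liver * hepatic + (1.0 - fm) * hepatic
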