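"""Structured run configuration and the file-based pipeline stages.

A single YAML/JSON document describes a run: drug parameter blocks
(induction, rifampin, rivaroxaban), the patient, the dosing regimens,
the solver settings, the exposure window and the output directory.  All
defaults equal the package's calibrated/published values, so an empty
``{}`` config reproduces the headline co-medication scenario for the
reference patient.  Unknown keys are rejected with field-path messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .engine import DDIModel, DoseEvent, Regimen, simulate
from .exposure import ExposureSummary, ExposureWindow
from .induction import InductionParams
from .regimens import (RegimenSpec, Scenario, evaluate_comedication_grid,
                       plan_initiation, plan_withdrawal)
from .rifampin import RifampinParams
from .rivaroxaban import Patient, RivaroxabanParams
from .synthetic import (ObservationSet, SyntheticCohortSpec, cohort_frame,
                        default_fixture_scenario, default_sampling_times,
                        make_cohort, make_observations, validation_report)

__all__ = ["RunConfig", "load_config", "build_model", "run_simulate",
           "run_validate", "run_optimize", "run_make_synthetic"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InductionBlock(_Block):
    e0: float = 1.0
    emax: float = 9.0
    ec50_um: float = 0.8
    kdeg: float = 0.0096
    fu_hep: float = 0.42
    kp_liver: float = 0.27
    fu_liver: float = 0.609
    fu_renal_site: float = 0.609
    mw_inducer: float = 822.94


class RifampinBlock(_Block):
    ka: float = 0.58
    v_per_kg: float = 0.33
    cl_t: float = 7.4
    cl_r: float = 1.5
    fm_cyp3a4: float = 0.2


class RivaroxabanBlock(_Block):
    ka: float = 1.4
    v: float = 50.0
    cl_total: float = 10.0
    f_cyp3a4: float = 0.18
    f_hep_other: float = 0.46
    f_pgp: float = 0.30
    f_gfr: float = 0.06
    crcl_ref: float = 104.0


class PatientBlock(_Block):
    age: float = 64.0
    weight: float = 60.3
    sex: str = "male"
    crcl: float = 118.0


class PatternBlock(_Block):
    """Repeating daily dosing pattern (days are 0-based)."""

    dose_mg: float
    frequency: str = "qd"
    start_day: int = 0
    n_days: int = 22


class RegimenBlock(_Block):
    """Either a repeating pattern or an explicit event list per drug."""

    pattern: PatternBlock | None = None
    events: list[dict] | None = None

    @model_validator(mode="after")
    def _one_of(self):
        if (self.pattern is None) == (self.events is None):
            raise ValueError("specify exactly one of 'pattern' or 'events'")
        return self

    def to_regimen(self, drug: str) -> Regimen:
        if self.pattern is not None:
            spec = RegimenSpec(self.pattern.dose_mg, self.pattern.frequency)
            return spec.regimen(drug, self.pattern.start_day, self.pattern.n_days)
        return Regimen(tuple(DoseEvent(time=e["time_h"], drug=drug,
                                       amount=e["amount_mg"])
                             for e in self.events))


class SolverBlock(_Block):
    dt: float = 0.05
    horizon_days: int = 22


class WindowBlock(_Block):
    cmax_lo: float = 91.0
    cmax_hi: float = 196.0
    auc_lo: float = 771.5
    auc_hi: float = 2118.2


class CohortBlock(_Block):
    n_patients: int = 6
    age_range: tuple[float, float] = (36.0, 71.0)
    weight_range: tuple[float, float] = (60.0, 67.0)
    crcl_range: tuple[float, float] = (52.0, 129.0)
    male_fraction: float = 0.5
    cv: float = 0.20


class RunConfig(_Block):
    """Top-level schema; every block has complete defaults."""

    induction: InductionBlock = Field(default_factory=InductionBlock)
    rifampin: RifampinBlock = Field(default_factory=RifampinBlock)
    rivaroxaban: RivaroxabanBlock = Field(default_factory=RivaroxabanBlock)
    patient: PatientBlock = Field(default_factory=PatientBlock)
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    riv_regimen: RegimenBlock = Field(default_factory=lambda: RegimenBlock(
        pattern=PatternBlock(dose_mg=15.0, frequency="bid")))
    rif_regimen: RegimenBlock = Field(default_factory=lambda: RegimenBlock(
        pattern=PatternBlock(dose_mg=600.0, frequency="qd")))
    solver: SolverBlock = Field(default_factory=SolverBlock)
    window: WindowBlock = Field(default_factory=WindowBlock)
    output_dir: str = "rivaddi_out"
    seed: int = 0


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or JSON config; ``None`` gives defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def build_model(config: RunConfig) -> DDIModel:
    return DDIModel(
        induction=InductionParams(**config.induction.model_dump()),
        rifampin=RifampinParams(**config.rifampin.model_dump()),
        rivaroxaban=RivaroxabanParams(**config.rivaroxaban.model_dump()),
        patient=Patient(**config.patient.model_dump()),
    )


def _window(config: RunConfig) -> ExposureWindow:
    return ExposureWindow(**config.window.model_dump())


def _manifest(config: RunConfig) -> dict:
    return {"package": "rivaddi", "version": __version__,
            "seed": config.seed, "config": config.model_dump(mode="json")}


def run_simulate(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate the configured scenario; write trajectory + exposure files."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_model(config)
    regimen = (config.riv_regimen.to_regimen("rivaroxaban")
               + config.rif_regimen.to_regimen("rifampin"))
    traj = simulate(model, regimen, config.solver.horizon_days * 24.0,
                    config.solver.dt)
    summary = ExposureSummary.from_trajectory(traj, _window(config))
    traj.to_frame().to_csv(outdir / "trajectory.csv", index=False,
                           float_format="%.10g")
    daily = summary.daily.copy()
    daily["flags"] = daily["flags"].map(lambda f: "|".join(sorted(f)))
    daily.to_csv(outdir / "exposure.csv", index=False, float_format="%.10g")
    report = {"manifest": _manifest(config),
              "ss_day": summary.ss_day,
              "cmax_ss": summary.cmax_ss, "auc_ss": summary.auc_ss,
              "daily": summary.to_records()}
    (outdir / "exposure.json").write_text(json.dumps(report, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(_manifest(config), indent=2))
    return report


def _patient_model(config: RunConfig, patient: Patient) -> DDIModel:
    return DDIModel(
        induction=InductionParams(**config.induction.model_dump()),
        rifampin=RifampinParams(**config.rifampin.model_dump()),
        rivaroxaban=RivaroxabanParams(**config.rivaroxaban.model_dump()),
        patient=patient)


def run_validate(config: RunConfig, observations_csv: str | Path,
                 outdir: str | Path | None = None) -> dict:
    """Fold-error report of an observation table against the fixture scenario.

    Each patient_id is validated against its own covariates: ids 1..n map
    onto the synthetic cohort regenerated from the config seed, matching
    the cohort written by :func:`run_make_synthetic`; unknown ids use the
    config's single-patient block.
    """
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = ObservationSet.from_csv(observations_csv)
    scenario = default_fixture_scenario(config.solver.horizon_days,
                                        config.solver.dt)
    spec = SyntheticCohortSpec(**config.cohort.model_dump(), seed=config.seed)
    cohort = make_cohort(spec)
    frames = []
    n_excluded = 0
    for pid, group in obs.frame.groupby("patient_id"):
        if 1 <= int(pid) <= len(cohort):
            model = _patient_model(config, cohort[int(pid) - 1])
        else:
            model = build_model(config)
        report = validation_report(ObservationSet(group.reset_index(drop=True)),
                                   model, scenario)
        frames.append(report.frame)
        n_excluded += report.n_excluded
    frame = pd.concat(frames, ignore_index=True)
    frac = float((frame["fold_error"] < 2.0).mean()) if len(frame) else float("nan")
    out = {"manifest": _manifest(config),
           "n_points": len(frame), "n_excluded": n_excluded,
           "fraction_fold_error_below_2": frac,
           "max_fold_error": float(frame["fold_error"].max()),
           "points": frame.to_dict(orient="records")}
    (outdir / "validation.json").write_text(json.dumps(out, indent=2))
    return out


def run_optimize(config: RunConfig, mode: str,
                 outdir: str | Path | None = None) -> dict:
    """Dispatch to the regimen searches; write a JSON recommendation."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_model(config)
    window = _window(config)
    dt = config.solver.dt
    horizon = config.solver.horizon_days
    if mode == "comed":
        recs = evaluate_comedication_grid(model, window=window,
                                          horizon_days=horizon, dt=dt)
        accepted = [r.candidate.label for r in recs if r.accepted]
        result = {"mode": mode, "accepted": accepted,
                  "recommendations": [r.as_dict() for r in recs]}
    elif mode == "initiation":
        plan = plan_initiation(model, window=window, horizon_days=horizon, dt=dt)
        result = {"mode": mode, **plan.as_dict()}
    elif mode == "withdrawal":
        plan = plan_withdrawal(model, window=window, dt=dt)
        result = {"mode": mode, **plan.as_dict()}
    else:
        raise ValueError(f"unknown optimize mode {mode!r}")
    result["manifest"] = _manifest(config)
    (outdir / f"optimize_{mode}.json").write_text(json.dumps(result, indent=2))
    return result


def run_make_synthetic(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Generate the synthetic cohort and fixture observations; write CSVs."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = SyntheticCohortSpec(**config.cohort.model_dump(), seed=config.seed)
    cohort = make_cohort(spec)
    cohort_frame(cohort).to_csv(outdir / "cohort.csv", index=False,
                                float_format="%.10g")
    scenario = default_fixture_scenario(config.solver.horizon_days,
                                        config.solver.dt)
    frames = []
    times = default_sampling_times()
    for i, patient in enumerate(cohort, start=1):
        model = DDIModel(
            induction=InductionParams(**config.induction.model_dump()),
            rifampin=RifampinParams(**config.rifampin.model_dump()),
            rivaroxaban=RivaroxabanParams(**config.rivaroxaban.model_dump()),
            patient=patient)
        traj = simulate(model, scenario.riv_regimen + scenario.rif_regimen,
                        scenario.horizon_days * 24.0, scenario.dt)
        obs = make_observations(traj, times, spec.cv, seed=config.seed + i,
                                patient_id=i)
        frames.append(obs.frame)
    all_obs = pd.concat(frames, ignore_index=True)
    all_obs.to_csv(outdir / "observations.csv", index=False,
                   float_format="%.10g")
    return {"manifest": _manifest(config), "n_patients": len(cohort),
            "n_observations": len(all_obs),
            "files": ["cohort.csv", "observations.csv"]}
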