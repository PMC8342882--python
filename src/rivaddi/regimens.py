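"""Dosing-regimen search: co-medication grid, initiation, withdrawal.

Three analyses answer the clinical questions around combining
rivaroxaban with rifampin:

* which maintenance regimen keeps steady-state exposure inside the
  reference window while rifampin is on board (grid search);
* how to start that regimen without overshooting on the first days,
  before induction has developed (day-1 initiation plan);
* how to step the dose back down after rifampin is withdrawn, while the
  induced enzyme pool de-induces over ~2 weeks (greedy per-day taper).

All three run on one virtual patient with the coupled induction model;
exposure is judged per 24-h calendar day against the reference window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import DDIModel, Regimen, Trajectory, simulate
from .exposure import (DEFAULT_SS_CAP_DAY, ExposureSummary, ExposureWindow,
                       classify_exposure, daily_metrics, interval_metrics)

__all__ = [
    "RegimenSpec",
    "Scenario",
    "DayRecord",
    "RegimenRecommendation",
    "InitiationPlan",
    "WithdrawalPlan",
    "simulate_scenario",
    "evaluate_comedication_grid",
    "plan_initiation",
    "plan_withdrawal",
    "DEFAULT_GRID",
    "DEFAULT_DAY1_CANDIDATES",
    "DEFAULT_TAPER_CANDIDATES",
]

_TIMES_OF_DAY = {"qd": (0.0,), "bid": (0.0, 12.0)}


@dataclass(frozen=True)
class RegimenSpec:
    """A (dose, frequency) shorthand such as '15 mg bid'."""

    dose_mg: float
    frequency: str

    def __post_init__(self) -> None:
        if self.frequency not in _TIMES_OF_DAY:
            raise ValueError(
                f"frequency must be one of {tuple(_TIMES_OF_DAY)}, got {self.frequency!r}")
        if self.dose_mg < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose_mg}")

    @property
    def times_of_day(self) -> tuple[float, ...]:
        return _TIMES_OF_DAY[self.frequency]

    @property
    def daily_total(self) -> float:
        return self.dose_mg * len(self.times_of_day)

    @property
    def label(self) -> str:
        return f"{self.dose_mg:g} mg {self.frequency}"

    def regimen(self, drug: str, start_day: int, n_days: int) -> Regimen:
        return Regimen.daily(drug, self.dose_mg, self.times_of_day, start_day, n_days)


DEFAULT_GRID = tuple(RegimenSpec(d, f) for d in (2.5, 5.0, 10.0, 15.0, 20.0)
                     for f in ("qd", "bid"))
DEFAULT_DAY1_CANDIDATES = (RegimenSpec(5.0, "qd"), RegimenSpec(10.0, "qd"),
                           RegimenSpec(15.0, "qd"), RegimenSpec(15.0, "bid"))
DEFAULT_TAPER_CANDIDATES = (RegimenSpec(10.0, "qd"), RegimenSpec(15.0, "qd"),
                            RegimenSpec(10.0, "bid"), RegimenSpec(15.0, "bid"))


@dataclass(frozen=True)
class Scenario:
    """A complete simulation request: both regimens, horizon, warm start."""

    riv_regimen: Regimen
    rif_regimen: Regimen = Regimen()
    horizon_days: int = 22
    dt: float = 0.05
    warm_state: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        end = max(self.riv_regimen.end_time, self.rif_regimen.end_time)
        if end > self.horizon_days * 24.0:
            raise ValueError(
                f"horizon ({self.horizon_days} d) does not cover the last dose "
                f"at {end} h")


def simulate_scenario(model: DDIModel, scenario: Scenario) -> Trajectory:
    return simulate(model, scenario.riv_regimen + scenario.rif_regimen,
                    scenario.horizon_days * 24.0, scenario.dt,
                    y0=scenario.warm_state)


@dataclass(frozen=True)
class DayRecord:
    """Exposure of one calendar day against the window."""

    day: int
    cmax: float
    auc: float
    flags: frozenset[str]

    @property
    def in_window(self) -> bool:
        return "in_window" in self.flags

    def as_dict(self) -> dict:
        return {"day": self.day, "cmax": self.cmax, "auc": self.auc,
                "flags": sorted(self.flags)}


def _day_record(df_row, window: ExposureWindow) -> DayRecord:
    return DayRecord(day=int(df_row["day"]), cmax=float(df_row["cmax"]),
                     auc=float(df_row["auc"]),
                     flags=classify_exposure(float(df_row["cmax"]),
                                             float(df_row["auc"]), window))


@dataclass(frozen=True)
class RegimenRecommendation:
    """Grid-search result for one candidate maintenance regimen."""

    candidate: RegimenSpec
    day1: DayRecord
    day2: DayRecord
    steady_state: DayRecord
    ss_day: int
    accepted: bool

    def as_dict(self) -> dict:
        return {"regimen": self.candidate.label,
                "day1": self.day1.as_dict(), "day2": self.day2.as_dict(),
                "steady_state": self.steady_state.as_dict(),
                "ss_day": self.ss_day, "accepted": self.accepted}


def _comed_trajectory(model: DDIModel, candidate: RegimenSpec,
                      rifampin_dose: float, horizon_days: int, dt: float,
                      day1: RegimenSpec | None = None) -> Trajectory:
    if day1 is None:
        riv = candidate.regimen("rivaroxaban", 0, horizon_days)
    else:
        riv = day1.regimen("rivaroxaban", 0, 1) + \
            candidate.regimen("rivaroxaban", 1, horizon_days - 1)
    rif = Regimen.daily("rifampin", rifampin_dose, (0.0,), 0, horizon_days)
    return simulate(model, riv + rif, horizon_days * 24.0, dt)


def _grid_rows(model, candidate, window, rifampin_dose, horizon_days, dt,
               day1=None) -> tuple[DayRecord, DayRecord, DayRecord, int]:
    traj = _comed_trajectory(model, candidate, rifampin_dose, horizon_days, dt,
                             day1=day1)
    summary = ExposureSummary.from_trajectory(traj, window)
    daily = summary.daily
    rec1 = _day_record(daily.iloc[0], window)
    rec2 = _day_record(daily.iloc[1], window)
    rec_ss = _day_record(daily.loc[daily["day"] == summary.ss_day].iloc[0], window)
    return rec1, rec2, rec_ss, summary.ss_day


def evaluate_comedication_grid(model: DDIModel,
                               candidates: tuple[RegimenSpec, ...] = DEFAULT_GRID,
                               window: ExposureWindow | None = None,
                               rifampin_dose: float = 600.0,
                               horizon_days: int = 22,
                               dt: float = 0.05) -> list[RegimenRecommendation]:
    """Simulate each candidate under co-medication from a cold start.

    Rifampin is dosed once daily at the same clock time as the morning
    rivaroxaban dose.  A candidate is accepted iff its steady-state Cmax
    and daily AUC are both inside the window.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    window = window or ExposureWindow()
    out = []
    for cand in candidates:
        rec1, rec2, rec_ss, ss_day = _grid_rows(
            model, cand, window, rifampin_dose, horizon_days, dt)
        out.append(RegimenRecommendation(
            candidate=cand, day1=rec1, day2=rec2, steady_state=rec_ss,
            ss_day=ss_day, accepted=rec_ss.in_window))
    return out


@dataclass(frozen=True)
class InitiationPlan:
    """Result of the day-1 dose-reduction search."""

    maintenance: RegimenSpec
    day1: RegimenSpec | None
    feasible: bool
    evaluations: tuple[dict, ...] = ()
    best_near_miss: dict | None = None

    def as_dict(self) -> dict:
        return {"maintenance": self.maintenance.label,
                "day1": self.day1.label if self.day1 else None,
                "feasible": self.feasible,
                "evaluations": list(self.evaluations),
                "best_near_miss": self.best_near_miss}


def _window_miss(rec: DayRecord, window: ExposureWindow) -> float:
    """Relative distance of a day record from the window (0 if inside)."""
    miss = 0.0
    if rec.auc < window.auc_lo:
        miss += (window.auc_lo - rec.auc) / window.auc_lo
    if rec.auc > window.auc_hi:
        miss += (rec.auc - window.auc_hi) / window.auc_hi
    if rec.cmax > window.cmax_hi:
        miss += (rec.cmax - window.cmax_hi) / window.cmax_hi
    return miss


def plan_initiation(model: DDIModel,
                    maintenance: RegimenSpec = RegimenSpec(15.0, "bid"),
                    candidates: tuple[RegimenSpec, ...] = DEFAULT_DAY1_CANDIDATES,
                    window: ExposureWindow | None = None,
                    rifampin_dose: float = 600.0,
                    horizon_days: int = 22,
                    dt: float = 0.05) -> InitiationPlan:
    """Pick the day-1 dose that keeps the whole course inside the window.

    For each candidate (largest daily total first, ties toward the
    higher single dose), day 1 uses the candidate and days >= 2 the
    maintenance regimen, with rifampin co-dosed throughout; the candidate
    is feasible iff day-1, day-2 and steady-state records are all in
    window.  Returns an explicit infeasible plan — carrying the best
    near-miss candidate and its metrics — when no candidate qualifies.
    """
    window = window or ExposureWindow()
    ordered = sorted(candidates,
                     key=lambda c: (c.daily_total, c.dose_mg), reverse=True)
    evaluations = []
    best = None
    best_miss = np.inf
    chosen = None
    for cand in ordered:
        rec1, rec2, rec_ss, ss_day = _grid_rows(
            model, maintenance, window, rifampin_dose, horizon_days, dt,
            day1=cand)
        ok = rec1.in_window and rec2.in_window and rec_ss.in_window
        ev = {"candidate": cand.label, "feasible": ok,
              "day1": rec1.as_dict(), "day2": rec2.as_dict(),
              "steady_state": rec_ss.as_dict(), "ss_day": ss_day}
        evaluations.append(ev)
        miss = sum(_window_miss(r, window) for r in (rec1, rec2, rec_ss))
        if miss < best_miss:
            best_miss, best = miss, ev
        if ok and chosen is None:
            chosen = cand
    return InitiationPlan(maintenance=maintenance, day1=chosen,
                          feasible=chosen is not None,
                          evaluations=tuple(evaluations),
                          best_near_miss=None if chosen else best)


@dataclass(frozen=True)
class WithdrawalPlan:
    """Greedy post-withdrawal taper plus the two fixed reference strategies."""

    schedule: tuple[dict, ...]
    immediate_switch: tuple[dict, ...]
    maintained: tuple[dict, ...]
    maintained_crossing_day: int | None
    immediate_regimen: RegimenSpec
    maintained_regimen: RegimenSpec

    def as_dict(self) -> dict:
        return {"schedule": list(self.schedule),
                "immediate_switch": {
                    "regimen": self.immediate_regimen.label,
                    "days": list(self.immediate_switch)},
                "maintained": {
                    "regimen": self.maintained_regimen.label,
                    "days": list(self.maintained),
                    "upper_bound_crossing_day": self.maintained_crossing_day}}


def _fixed_strategy_days(model, spec: RegimenSpec, warm_state, n_days, dt,
                         window) -> list[DayRecord]:
    riv = spec.regimen("rivaroxaban", 0, n_days)
    traj = simulate(model, riv, n_days * 24.0, dt, y0=warm_state)
    daily = daily_metrics(traj, window)
    return [_day_record(row, window) for _, row in daily.iterrows()]


def plan_withdrawal(model: DDIModel,
                    n_days: int = 7,
                    candidates: tuple[RegimenSpec, ...] = DEFAULT_TAPER_CANDIDATES,
                    window: ExposureWindow | None = None,
                    comedication: RegimenSpec = RegimenSpec(15.0, "bid"),
                    immediate: RegimenSpec = RegimenSpec(10.0, "qd"),
                    rifampin_dose: float = 600.0,
                    pre_days: int = DEFAULT_SS_CAP_DAY,
                    fixed_horizon_days: int = 14,
                    dt: float = 0.05,
                    warm_state=None) -> WithdrawalPlan:
    """Search a day-by-day taper after rifampin withdrawal.

    The system is first driven to co-medication steady state
    (``comedication`` + rifampin for ``pre_days``), then rifampin stops.
    For each post-withdrawal day the lowest-daily-dose candidate whose
    Cmax and AUC stay in window is chosen, given the de-induction
    trajectory carried over from the previous days; an infeasible day is
    flagged and continued with the nearest-miss candidate.  The two fixed
    reference strategies (immediate switch to ``immediate``; maintained
    ``comedication``) are evaluated over ``fixed_horizon_days``, and for
    the maintained strategy the first day whose AUC exceeds the upper
    window bound is reported.
    """
    window = window or ExposureWindow()
    if warm_state is None:
        pre = _comed_trajectory(model, comedication, rifampin_dose, pre_days, dt)
        warm_state = tuple(pre.final_state)
    ordered = sorted(candidates, key=lambda c: (c.daily_total, c.dose_mg))
    state = tuple(float(v) for v in warm_state)
    schedule = []
    for day in range(1, n_days + 1):
        chosen = None
        chosen_rec = None
        chosen_state = None
        best = None  # (miss, spec, record, state)
        for cand in ordered:
            riv = cand.regimen("rivaroxaban", 0, 1)
            traj = simulate(model, riv, 24.0, dt, y0=state)
            cmax, auc = interval_metrics(traj, 0.0, 24.0)
            rec = DayRecord(day=day, cmax=cmax, auc=auc,
                            flags=classify_exposure(cmax, auc, window))
            miss = _window_miss(rec, window)
            if best is None or miss < best[0]:
                best = (miss, cand, rec, tuple(traj.final_state))
            if rec.in_window:
                chosen, chosen_rec, chosen_state = cand, rec, tuple(traj.final_state)
                break
        feasible = chosen is not None
        if not feasible:
            _, chosen, chosen_rec, chosen_state = best
        schedule.append({"day": day, "regimen": chosen.label,
                         "daily_dose_mg": chosen.daily_total,
                         "feasible": feasible, **chosen_rec.as_dict()})
        state = chosen_state
    imm = _fixed_strategy_days(model, immediate, warm_state,
                               fixed_horizon_days, dt, window)
    kept = _fixed_strategy_days(model, comedication, warm_state,
                                fixed_horizon_days, dt, window)
    crossing = next((r.day for r in kept if r.auc > window.auc_hi), None)
    return WithdrawalPlan(
        schedule=tuple(schedule),
        immediate_switch=tuple(r.as_dict() for r in imm),
        maintained=tuple(r.as_dict() for r in kept),
        maintained_crossing_day=crossing,
        immediate_regimen=immediate,
        maintained_regimen=comedication)
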