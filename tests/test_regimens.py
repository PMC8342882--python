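"""Regimen searches: co-medication grid, initiation plan, withdrawal taper."""

import numpy as np
import pytest

from rivaddi import (DDIModel, ExposureWindow, Regimen, RegimenSpec,
                     evaluate_comedication_grid, plan_initiation,
                     plan_withdrawal, simulate)
from rivaddi.regimens import DEFAULT_GRID


@pytest.fixture(scope="module")
def grid(model, window):
    return evaluate_comedication_grid(model, window=window)


@pytest.fixture(scope="module")
def withdrawal(model, window):
    return plan_withdrawal(model, window=window)


class TestComedicationGrid:
    def test_unique_accepted_regimen_is_15_bid(self, grid):
        accepted = [r.candidate.label for r in grid if r.accepted]
        assert accepted == ["15 mg bid"]

    def test_accepted_regimen_steady_state_in_window(self, grid, window):
        rec = next(r for r in grid if r.accepted)
        assert rec.steady_state.cmax <= window.cmax_hi
        assert rec.steady_state.auc >= window.auc_lo
        assert rec.steady_state.auc <= window.auc_hi

    def test_15_bid_first_day_overshoots(self, grid, window):
        rec = next(r for r in grid if r.candidate.label == "15 mg bid")
        assert rec.day1.auc > window.auc_hi
        assert "bleeding_risk" in rec.day1.flags

    def test_monotone_dose_response(self, grid):
        by_label = {r.candidate.label: r for r in grid}
        for freq in ("qd", "bid"):
            doses = [2.5, 5.0, 10.0, 15.0, 20.0]
            for lo, hi in zip(doses, doses[1:]):
                a = by_label[f"{lo:g} mg {freq}"]
                b = by_label[f"{hi:g} mg {freq}"]
                for day in ("day1", "day2", "steady_state"):
                    assert getattr(b, day).cmax > getattr(a, day).cmax
                    assert getattr(b, day).auc > getattr(a, day).auc

    def test_infinite_window_accepts_all(self, model):
        wide = ExposureWindow(cmax_lo=0.0, cmax_hi=1e9, auc_lo=0.0, auc_hi=1e12)
        recs = evaluate_comedication_grid(model, window=wide)
        assert all(r.accepted for r in recs)

    def test_sliver_window_accepts_none(self, model):
        tiny = ExposureWindow(cmax_lo=1.0, cmax_hi=1.0001,
                              auc_lo=1.0, auc_hi=1.0001)
        recs = evaluate_comedication_grid(model, window=tiny)
        assert not any(r.accepted for r in recs)

    def test_empty_candidate_list_rejected(self, model):
        with pytest.raises(ValueError):
            evaluate_comedication_grid(model, candidates=())


class TestInitiationPlan:
    def test_default_calibration_near_miss(self, model, window):
        """Under the default calibration the strict contract (day 1, day 2
        and steady state all in window) is infeasible: the maintenance
        regimen's day-2 Cmax sits a fraction of a percent above the upper
        bound whatever the day-1 dose.  The plan must say so explicitly
        and identify 10 mg qd as the best near-miss day-1 dose, with
        day-2 Cmax as the only breach."""
        plan = plan_initiation(model, window=window)
        assert not plan.feasible
        assert plan.day1 is None
        assert plan.best_near_miss is not None
        assert plan.best_near_miss["candidate"] == "10 mg qd"
        near = plan.best_near_miss
        assert near["day1"]["flags"] == ["in_window"]
        assert near["steady_state"]["flags"] == ["in_window"]
        # the single breach is the day-2 peak, by well under 1 %
        assert near["day2"]["flags"] == ["bleeding_risk"]
        assert near["day2"]["cmax"] == pytest.approx(window.cmax_hi, rel=0.01)
        assert near["day2"]["auc"] <= window.auc_hi

    def test_infinite_window_returns_highest_candidate(self, model):
        wide = ExposureWindow(cmax_lo=0.0, cmax_hi=1e9, auc_lo=0.0, auc_hi=1e12)
        plan = plan_initiation(model, window=wide)
        assert plan.feasible
        assert plan.day1.label == "15 mg bid"  # highest daily total wins ties

    def test_empty_candidate_list_is_infeasible(self, model, window):
        plan = plan_initiation(model, candidates=(), window=window)
        assert not plan.feasible
        assert plan.day1 is None


class TestWithdrawalPlan:
    def test_immediate_switch_underexposed_first_five_days(self, withdrawal, window):
        first5 = [d for d in withdrawal.immediate_switch if d["day"] <= 5]
        assert len(first5) == 5
        assert all(d["auc"] < window.auc_lo for d in first5)

    def test_maintained_regimen_eventually_overshoots(self, withdrawal, window):
        assert withdrawal.maintained_crossing_day is not None
        crossing = withdrawal.maintained_crossing_day
        days = {d["day"]: d for d in withdrawal.maintained}
        assert days[crossing]["auc"] > window.auc_hi
        assert days[crossing - 1]["auc"] <= window.auc_hi

    def test_greedy_schedule_in_window_each_day(self, withdrawal):
        assert all(d["feasible"] for d in withdrawal.schedule)
        assert all(d["flags"] == ["in_window"] for d in withdrawal.schedule)

    def test_taper_starts_high_and_steps_down(self, withdrawal):
        totals = [d["daily_dose_mg"] for d in withdrawal.schedule]
        assert totals[0] == 30.0  # day 1 still needs the full induced dose
        assert min(totals) < totals[0]

    def test_auc_only_window_gives_non_increasing_daily_dose(self, model):
        # with the Cmax constraint relaxed, de-induction only raises
        # exposure at fixed dose, so the greedy taper never steps back up
        auc_only = ExposureWindow(cmax_lo=0.0, cmax_hi=1e9,
                                  auc_lo=771.5, auc_hi=2118.2)
        plan = plan_withdrawal(model, window=auc_only)
        totals = [d["daily_dose_mg"] for d in plan.schedule]
        assert all(b <= a for a, b in zip(totals, totals[1:]))

    def test_wide_window_picks_lowest_candidate_daily(self, model):
        wide = ExposureWindow(cmax_lo=0.0, cmax_hi=1e9, auc_lo=0.0, auc_hi=1e12)
        plan = plan_withdrawal(model, n_days=3, window=wide)
        assert all(d["daily_dose_mg"] == 10.0 for d in plan.schedule)

    def test_warm_start_consistency(self, model):
        """Chaining co-medication then withdrawal equals one continuous
        simulation of the same dosing history."""
        pre_days, post_days = 6, 3
        comed = (Regimen.daily("rivaroxaban", 15.0, (0.0, 12.0), 0, pre_days)
                 + Regimen.daily("rifampin", 600.0, (0.0,), 0, pre_days))
        pre = simulate(model, comed, pre_days * 24.0, 0.05)
        post = simulate(model, Regimen.daily("rivaroxaban", 10.0, (0.0,), 0, post_days),
                        post_days * 24.0, 0.05, y0=pre.final_state)
        whole = simulate(
            model,
            comed + Regimen.daily("rivaroxaban", 10.0, (0.0,), pre_days, post_days),
            (pre_days + post_days) * 24.0, 0.05)
        tail = whole.y[pre_days * 480:]
        assert np.allclose(tail, post.y, rtol=1e-10, atol=1e-12)


class TestRegimenSpec:
    def test_labels_and_totals(self):
        assert RegimenSpec(15.0, "bid").label == "15 mg bid"
        assert RegimenSpec(15.0, "bid").daily_total == 30.0
        assert RegimenSpec(10.0, "qd").daily_total == 10.0

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            RegimenSpec(10.0, "tid")

    def test_default_grid_composition(self):
        assert len(DEFAULT_GRID) == 10
        assert len({s.label for s in DEFAULT_GRID}) == 10
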