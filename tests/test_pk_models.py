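"""Drug disposition models against closed-form one-compartment oracles."""

import math

import numpy as np
import pytest

from rivaddi import (DDIModel, EnzymeState, InductionParams, Patient,
                     Regimen, RifampinParams, RifampinState,
                     RivaroxabanParams, induced_total_clearance,
                     liver_site_concentration, renal_site_concentration,
                     rifampin_rhs, rivaroxaban_rhs, simulate)
from conftest import bateman


class TestRifampinModel:
    def test_empty_system_has_zero_derivative(self):
        da, dc = rifampin_rhs(RifampinState(0.0, 0.0), 3.0, RifampinParams(), 60.0)
        assert da == 0.0 and dc == 0.0

    def test_single_dose_matches_bateman(self, frozen_model):
        # 600 mg, activity pinned at baseline, 60.3 kg patient:
        # ke = 7.4 / (0.33*60.3); compare the full curve within 0.1 %
        regimen = Regimen.repeating("rifampin", 600.0, 24.0, 0.0, 1)
        traj = simulate(frozen_model, regimen, 24.0, 0.05)
        v = 0.33 * frozen_model.patient.weight
        expected = bateman(traj.t, 600.0, 0.58, v, 7.4)
        scale = expected.max()
        assert np.max(np.abs(traj.rif_conc_mgl - expected)) / scale < 1e-3

    def test_elimination_half_life(self):
        # ke = CL/(V*BW) = 7.4/19.8 at 60 kg -> t1/2 = 1.855 h
        ke = 7.4 / (0.33 * 60.0)
        assert math.log(2) / ke == pytest.approx(1.855, abs=0.002)

    def test_dose_proportionality_at_fixed_activity(self, frozen_model):
        r1 = Regimen.repeating("rifampin", 300.0, 24.0, 0.0, 3)
        r2 = Regimen.repeating("rifampin", 600.0, 24.0, 0.0, 3)
        t1 = simulate(frozen_model, r1, 72.0, 0.05)
        t2 = simulate(frozen_model, r2, 72.0, 0.05)
        assert np.allclose(2.0 * t1.rif_conc_mgl, t2.rif_conc_mgl, rtol=1e-9)

    def test_no_cyp_fraction_means_no_self_induction(self):
        # with fm = 0 the total clearance is activity-independent, so a
        # multi-dose run equals superposed single doses despite induction
        model = DDIModel(rifampin=RifampinParams(fm_cyp3a4=0.0))
        multi = simulate(model, Regimen.repeating("rifampin", 600.0, 24.0, 0.0, 4),
                         120.0, 0.05)
        single = [simulate(model, Regimen.repeating("rifampin", 600.0, 24.0, s, 1),
                           120.0, 0.05) for s in (0.0, 24.0, 48.0, 72.0)]
        superposed = sum(s.rif_conc_mgl for s in single)
        scale = superposed.max()
        assert np.max(np.abs(multi.rif_conc_mgl - superposed)) / scale < 1e-6

    def test_autoinduction_decreases_daily_auc(self, model):
        traj = simulate(model, Regimen.repeating("rifampin", 600.0, 24.0, 0.0, 14),
                        14 * 24.0, 0.05)
        daily_auc = [np.trapezoid(traj.rif_conc_mgl[480 * d:480 * (d + 1) + 1],
                                  traj.t[480 * d:480 * (d + 1) + 1])
                     for d in range(14)]
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(daily_auc, daily_auc[1:]))
        # and the day-over-day change flattens out (approach to steady state)
        assert daily_auc[-2] - daily_auc[-1] < 0.02 * daily_auc[-1]

    def test_negative_body_weight_rejected(self):
        with pytest.raises(ValueError):
            rifampin_rhs(RifampinState(1.0, 1.0), 1.0, RifampinParams(), -60.0)


class TestSiteConcentrations:
    def test_zero_plasma(self, induction_params):
        assert liver_site_concentration(0.0, induction_params) == 0.0

    def test_molar_conversion_with_partition(self, induction_params):
        # 0.82294 mg/L is 1.0 µM at MW 822.94; times Kp 0.27
        assert liver_site_concentration(0.82294, induction_params) == pytest.approx(
            0.27, rel=1e-12)
        assert liver_site_concentration(10.0, induction_params) == pytest.approx(
            3.281, rel=1e-3)

    def test_renal_site_uses_plasma(self, induction_params):
        assert renal_site_concentration(0.82294, induction_params) == pytest.approx(
            1.0, rel=1e-12)


class TestRivaroxabanClearance:
    def test_baseline_identity(self):
        cl = induced_total_clearance(RivaroxabanParams(), EnzymeState(1.0, 1.0),
                                     Patient(crcl=104.0))
        assert cl == pytest.approx(10.0, rel=1e-12)

    def test_six_fold_induction(self):
        cl = induced_total_clearance(RivaroxabanParams(), EnzymeState(6.0, 6.0),
                                     Patient(crcl=104.0))
        assert cl == pytest.approx(34.0, rel=1e-12)

    def test_renal_impairment_halves_renal_pathways(self):
        cl = induced_total_clearance(RivaroxabanParams(), EnzymeState(1.0, 1.0),
                                     Patient(crcl=52.0))
        assert cl == pytest.approx(8.2, rel=1e-12)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            RivaroxabanParams(f_cyp3a4=0.2, f_hep_other=0.46, f_pgp=0.30,
                              f_gfr=0.06)


class TestRivaroxabanModel:
    def test_zero_state_zero_derivative(self):
        da, dc = rivaroxaban_rhs(0.0, 0.0, EnzymeState(), RivaroxabanParams(),
                                 Patient())
        assert da == 0.0 and dc == 0.0

    def test_single_dose_matches_bateman(self, frozen_model):
        model = DDIModel(induction=InductionParams(emax=1e-12),
                         patient=Patient(crcl=104.0))
        regimen = Regimen.repeating("rivaroxaban", 10.0, 24.0, 0.0, 1)
        traj = simulate(model, regimen, 48.0, 0.05)
        expected = bateman(traj.t, 10.0, 1.4, 50.0, 10.0) * 1000.0  # ng/ml
        assert np.max(np.abs(traj.riv_conc_ngml - expected)) / expected.max() < 1e-3

    def test_single_dose_auc_is_dose_over_clearance(self):
        model = DDIModel(induction=InductionParams(emax=1e-12),
                         patient=Patient(crcl=104.0))
        traj = simulate(model, Regimen.repeating("rivaroxaban", 10.0, 24.0, 0.0, 1),
                        240.0, 0.05)
        auc = np.trapezoid(traj.riv_conc_ngml, traj.t)
        assert auc == pytest.approx(1000.0, rel=2e-3)  # 10 mg / 10 L/h

    def test_higher_activity_lowers_exposure(self):
        aucs = []
        for et in (1.0, 2.0, 4.0):
            cl = induced_total_clearance(RivaroxabanParams(),
                                         EnzymeState(et, et), Patient(crcl=104.0))
            aucs.append(10.0e6 / cl / 1000.0)  # dose/CL in ng·h/ml
        assert aucs[0] > aucs[1] > aucs[2]
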