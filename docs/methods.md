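# Methods

## Model structure

The package couples three submodels into one six-state ODE system
`[rif_gut, rif_central, riv_gut, riv_central, et_liver, et_renal]`.

**Induction turnover.** Relative enzyme activity at each site follows a
zero-order-synthesis / first-order-degradation turnover model in which
the inducer stimulates synthesis through an Emax/EC50 term. At constant
inducer concentration the equation is linear in the activity, so the
solution is exactly exponential with rate `kdeg` toward
`E0·(1 + Emax·occ)`; the activity is bounded between `E0` and
`E0·(1+Emax)` for any non-negative drive, and washout after the inducer
disappears decays with half-life `ln 2 / kdeg ≈ 72.2 h`. These closed
forms serve as independent oracles in the test suite. The in-vitro EC50
is corrected by the hepatocyte-incubation free fraction (`fu_hep`
= 0.42) in the denominator at both sites; the in-vivo drive uses the
site-specific unbound fraction. P-gp induction is assumed to share the
CYP3A4 parameters (both are PXR-regulated), evaluated at the renal site.

**Site concentrations.** The hepatic drive uses the liver concentration
`Kp_liver · C_plasma` (Kp = 0.27); no renal partition coefficient is
available, so the renal drive uses the plasma concentration directly
with the hepatic unbound fraction (0.609) — the conservative default,
both configurable. Mass-based plasma concentrations (mg/L) are bridged
to the molar EC50 scale with rifampin's molar mass (822.94 g/mol).

**Rifampin.** One compartment, first-order absorption and elimination;
parameters are apparent oral values (no explicit bioavailability term).
Self-induction enters through the clearance decomposition
`CL(E) = CL_R + fm·E·(CL_t − CL_R) + (1 − fm)·(CL_t − CL_R)`, which
returns the uninduced total clearance exactly at `E = 1`. With `fm = 0`
the model is linear and multi-dose trajectories superpose — a property
test. Default regimen: 600 mg once daily at the same clock time as the
morning rivaroxaban dose.

**Rivaroxaban.** The victim is a reduced one-compartment model with the
apparent total clearance partitioned across four routes. The published
whole-body description of rivaroxaban is not reproduced here; instead
the pathway fractions are *calibration choices* satisfying two
constraints: (a) uninduced 10 mg qd steady-state exposure for a
reference-renal-function patient sits mid-window (Cmax ≈ 146 ng/ml, AUC
≈ 1000 ng·h/ml inside 91–196 / 771.5–2118.2), and (b) the steady-state
induced/baseline clearance ratio under rifampin 600 mg qd is ≈ 3, so
that tripling the daily dose (10 mg qd → 15 mg bid) restores in-window
exposure. Defaults: `Ka = 1.4 h⁻¹`, `V = 50 L`, `CL_total = 10 L/h`,
fractions (CYP3A4, other hepatic, P-gp, GFR) = (0.18, 0.46, 0.30,
0.06), `crcl_ref = 104 ml/min`. Renal function scales both renal routes
linearly in `crcl/crcl_ref`. Under these defaults the simulated
steady-state activities for the reference patient are
`Et_liver ≈ 3.6`, `Et_renal ≈ 4.7` and the induced/baseline clearance
ratio is ≈ 2.8.

## Parameters that matter

| parameter | default | units | note |
|---|---|---|---|
| Emax | 9.0 | fold | maximal synthesis stimulation |
| EC50 | 0.8 | µM | in vitro, corrected by fu_hep = 0.42 |
| kdeg | 0.0096 | 1/h | sets the ~72 h induction/washout half-life |
| Kp_liver / fu_liver | 0.27 / 0.609 | — | hepatic drive of the inducer |
| rifampin Ka, V, CLt, CLR, fm | 0.58 h⁻¹, 0.33 L/kg, 7.4, 1.5 L/h, 0.2 | | apparent oral values |
| rivaroxaban Ka, V, CL | 1.4 h⁻¹, 50 L, 10 L/h | | calibration choices (see above) |
| pathway fractions | 0.18/0.46/0.30/0.06 | — | calibration choices |
| exposure window | 91–196 ng/ml; 771.5–2118.2 ng·h/ml | | published 5th–95th percentile for 10 mg qd |
| solver step dt | 0.05 | h | see numerics |

## Numerics

Classic fixed-step RK4; the system is non-stiff (fastest rate constant
1.4 h⁻¹), and at dt = 0.05 h a step-halving audit (`halve_step_check`)
shows < 0.1 % change in rivaroxaban concentration on the co-medication
scenario; tests also verify fourth-order error decay and a cross-check
against an adaptive RK45 integration of the same right-hand side. Dose
times are snapped to the nearest grid point (warning beyond 1e-9 h) and
added to the depot before the step beginning at that time; same-time
events commute. Initial conditions are zero drug, activities at `E0`,
unless a warm-start state (needed for withdrawal scenarios) is given.
Non-finite or negative states abort with the first bad time. AUC uses
the trapezoid rule on the solver grid; Cmax is the max sampled point.

Steady state is declared on the first day whose AUC changes < 1 % from
the previous day, capped at day 21 of co-medication (≈ five induction
half-lives); an alternating series falls back to the final day with a
warning. Exposure windows are evaluated per 24-h calendar day for both
qd and bid regimens (the window derives from a once-daily exposure, so
bid days aggregate both dosing intervals).

## Regimen searches

*Grid*: each candidate in {2.5, 5, 10, 15, 20 mg} × {qd, bid} is
simulated from a cold start with rifampin 600 mg qd for 22 days;
acceptance requires steady-state Cmax and AUC both in window.
*Initiation*: candidates for day 1 ({5, 10, 15 mg qd, 15 mg bid},
largest daily total first, ties to the higher single dose) are feasible
only if day 1, day 2 and steady state are all in window; if none
qualifies, the plan is explicitly infeasible and carries the best
near-miss candidate with its metrics. Under the default calibration the
strict contract is in fact infeasible: the maintenance regimen's day-2
Cmax computes to ≈ 196.6 ng/ml, a fraction of a percent above the
196 ng/ml bound, independent of the day-1 dose (day-1 carryover at the
day-2 peak is < 1 ng/ml). The best near-miss is 10 mg qd, whose only
breach is that day-2 peak; this is the same calibration sensitivity
that affects the withdrawal crossing day, and the package reports it
rather than rounding it away.
*Withdrawal*: the system is driven to co-medication steady state
(15 mg bid + rifampin, 21 days), rifampin stops, and a greedy per-day
search picks the lowest daily dose from {10 qd, 15 qd, 10 bid, 15 bid}
keeping that day in window given the carried-over de-induction state;
infeasible days are flagged with nearest-miss metrics. The two fixed
reference strategies (immediate switch to 10 mg qd; maintained
15 mg bid) are evaluated over 14 days and the first day the maintained
strategy's AUC crosses the upper bound is reported, not asserted — it
depends on the calibrated fractions. Note the greedy schedule is
non-increasing in daily dose only while AUC is the binding constraint;
once de-induction lowers clearance enough, a single 15 mg dose peaks
above the Cmax bound and the search legitimately steps sideways to
10 mg bid (smaller doses, same daily total neighbourhood).

## Synthetic data

The generator emulates the structure of the clinical validation data:
patients drawn uniformly from the reported characteristic ranges (age
36–71 y, weight 60–67 kg, CrCl 52–129 ml/min, 3:3 sex split at n = 6),
a canonical dosing history covering all three phases (rivaroxaban
10 mg qd from day 0; rifampin 600 mg qd days 3–17), sparse samples at
2/4/8/12/24 h after selected morning doses, and multiplicative
lognormal residual error with CV = 0.20
(`sigma = sqrt(ln(1 + cv²))`, so the arithmetic CV equals the nominal
value — verified by Monte-Carlo in the tests). Everything is
reproducible from (spec, seed). What it does **not** emulate:
inter-individual variability in the PK parameters themselves,
inter-occasion variability, assay error structure at low
concentrations, or covariate effects beyond renal function — so passing
self-validation (≈ 99.9 % of fold errors < 2 at CV 0.2) demonstrates
internal consistency of the pipeline, not predictive accuracy in real
patients.

## Problem sizes

Default analyses use 22-day horizons for co-medication (enough for the
~72 h induction half-life to settle within the 1 % daily-AUC
criterion), 21 pre-withdrawal days plus 14 post-withdrawal days for the
taper analyses, and dt = 0.05 h throughout; a full regimen analysis
runs in seconds on one core.

## Limitations

* The victim model is a reduced disposition model; organ-level
  distribution, BCRP, gut-wall induction and two-compartment kinetics
  are out of scope, so absolute predictions inherit the calibration
  choices above. Quantities sensitive to them (the exact day-2 peak,
  the exact post-withdrawal crossing day) should be read as
  model-relative, and the package surfaces them as computed values
  with flags rather than hard-coded conclusions.
* No inter-individual variability is estimated or simulated; all
  regimen analyses are for a single virtual patient.
* Trough-based evaluation is deliberately not used (the published
  trough percentile range is too wide to be a useful target); AUC and
  Cmax are the exposure variables.
* Induction parameters of P-gp are assumed identical to CYP3A4; no
  renal-specific partition or unbound fraction is available.
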