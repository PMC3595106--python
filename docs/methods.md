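# Methods

This note documents the models behind `tgcsim`, the parameters that
matter, the design choices that were genuinely open, and what the test
suite does and does not demonstrate about real patients.

## Virtual patient

The patient is a deterministic ODE system — a minimal (Bergman-type)
glucose–insulin model with two extensions needed by the ICU protocol:
an interstitial glucose compartment for the subcutaneous sensor to
read, and a time-varying insulin-resistance multiplier for the
"diabetes of injury" that follows cardiac surgery.

```
dG/dt      = -(p1 + X) G + (EGP + Ra) / (V_g W)        [mmol/L per h]
dX/dt      = p2 (S_I,eff u - X)                         [1/h per h]
dG_isf/dt  = (G - G_isf) 60 / tau_sen                   [mmol/L per h]
S_I,eff    = S_I / IR(t),  IR(t) = 1 + (IR_0 - 1) e^(-t/t_IR)
```

States: plasma glucose `G`, remote insulin action `X`, interstitial
glucose `G_isf`. Inputs: IV insulin `u` (IU/h) and exogenous glucose
appearance `Ra` (mmol/h) converted from the dextrose/carbohydrate rates
with a glucose molar mass of 180.16 g/mol. `tau_sen = 0` is an exact
no-lag bypass (`G_isf ≡ G`), used in experiments that require the
sensor-facing signal to equal plasma glucose.

Default parameters (all overridable):

| parameter | default | unit | role |
|---|---|---|---|
| `p1` | 0.25 | 1/h | glucose effectiveness (insulin-independent clearance) |
| `p2` | 0.5 | 1/h | insulin-action rate constant |
| `s_i` | 0.2 | (1/h)/(IU/h) | insulin sensitivity |
| `v_g_l_per_kg` | 0.16 | L/kg | glucose distribution volume |
| `tau_sen_min` | 10 | min | plasma→interstitium lag |
| `ir_mult0` | 2 | – | initial insulin-resistance multiplier |
| `ir_decay_h` | 12 | h | resistance decay time constant |
| `g0_mmol_l` | 9 | mmol/L | baseline (admission) glucose |
| `egp_mmol_h` | `p1·g0·V_g·W` | mmol/h | endogenous glucose production |

Two of these deserve comment.

*Glucose effectiveness.* Minimal-model estimates of glucose
effectiveness in adults are of order 0.01–0.03 per **minute**
(0.6–1.8/h). We use 0.25/h — deliberately at the low, insulin-resistant
end — because a critically low value (two orders of magnitude below
physiology) turns the model into a near-integrator: glucose turnover
takes days, any post-infusion dip becomes irrecoverable hypoglycemia,
and no controller of this architecture can satisfy the protocol's
safety requirements. At 0.25/h the implied endogenous production
(~29 mmol/h ≈ 5.2 g/h for an 80-kg patient) is physiological.

*Endogenous glucose production.* `EGP` defaults to the value that makes
the admission glucose `g0` the steady state of the unforced system
(no insulin, no infusion). The patient therefore arrives at the ICU in
equilibrium at their stress-hyperglycemic baseline; the continuous
dextrose infusion then pushes glycemia upward during the 105-min sensor
run-in (to ~14 mmol/L for the default patient) until insulin starts.

*Dextrose dosing.* The infusion is 2.5 g of glucose per kg of ideal
body weight (height in cm − 100) **per 24 h**, running for the first
18 h. A per-hour reading of that dose would be ~1.75 L/h of 10%
dextrose — not survivable — so the per-day interpretation is the only
physiologic one; the dose and duration are configurable.

Integration is fixed-step RK4 at 1 min with exogenous inputs held
constant within a step. Negative state components are clamped to zero
with a logged warning; non-finite states raise. Halving the step
changes the 24-h endpoint glucose by < 1e-4 mmol/L.

### Cohort generator

`make_cohort` samples what the protocol needs and nothing more:
heights/BMIs typical of elderly elective cardiac-surgery patients,
lognormal baseline glucose with median ≈ 9 mmol/L, lognormal insulin
sensitivity, ~25% prevalence of type 2 diabetes (diabetics get lower
`s_i`, higher `g0`), and lognormal insulin-resistance amplitude and
decay. It does **not** emulate meals, counter-regulation, drug effects
(steroids, catecholamines), renal excretion, or measurement error in
the arterial reference — so passing tests demonstrate the *protocol and
controller logic* under plausible kinetics, not clinical performance.

## CGM sensor

The displayed value is `gain · drift(t) · G_isf + noise` with
`drift(t) = 1 + d·(t − t_cal)/60`; calibration resets the gain so the
next noiseless reading equals the arterial reference (within
`cal_error_sd`) and restarts the drift clock. Defaults:
noise SD 0.4 mmol/L, drift 0.5%/h, calibration residual 0.15 mmol/L,
failure probability 1/12 per 24 h (failure is absorbing and is detected
at the next read), run-in 105 min, first valid reading at the first
5-min grid point at or after run-in. The uncalibrated initial gain is
lognormal (log-SD 0.2), which is why the initial calibration matters.

A consequence worth stating: with the controller holding glycemia in
range, essentially all simulated reference/CGM pairs fall in Clarke
zones A+B (the unacceptable zones require hypo- or hyperglycemic
*references* — e.g. zone D needs a reference below 70 mg/dL). Clinical
reports of ~97.5% A+B with a few D-zone points reflect real
hypoglycemic excursions that this benign, well-controlled simulation
largely prevents. We keep the error model honest rather than inflating
it to manufacture D-zone points.

## Clarke error-grid analysis

The standard 1987 zone geometry, evaluated in mg/dL
(1 mmol/L = 18.016 mg/dL):

* **A** `|e−r| ≤ 0.2r`, or both below 70;
* **E** `r ≤ 70 ∧ e ≥ 180`, or `r ≥ 180 ∧ e ≤ 70`;
* **C** `70 ≤ r ≤ 290 ∧ e ≥ r+110`, or `130 ≤ r ≤ 180 ∧ e ≤ 1.4r−182`;
* **D** `r ≥ 240 ∧ 70 ≤ e ≤ 180`, or `r ≤ 70 ∧ 70 ≤ e ≤ 180`;
* **B** otherwise.

All inequalities are non-strict and overlaps resolve by the precedence
A > E > C > D > B (ties go to the better zone). Comparisons carry a
1e-6 mg/dL tolerance so that points mathematically *on* a boundary
(e.g. 6.0 = 1.2 × 5.0 mmol/L) classify inclusively regardless of
floating-point conversion error; the test suite verifies exact
agreement with an independent polygon-membership oracle on the full
0.1 mmol/L grid over (0, 45]². Summary percentages are computed from
exact counts and rounded half-up to one decimal.

## Controller

The controller's internal model is the same structural family as the
patient but deliberately mismatched: fixed population kinetics
(`p1 = 0.25/h`, `p2 = 0.5/h`, `V_g = 0.16 L/kg`, EGP scaled to a
9 mmol/L reference), no knowledge of the resistance decay, and a single
estimated parameter — the effective insulin sensitivity. Closed-loop
tests therefore exercise robustness, not self-fulfilling prediction.

*Estimation.* At each glucose input the model is propagated from the
previous measurement through the recorded insulin/carbohydrate inputs;
the scalar RLS update uses the prediction residual and the sensitivity
of the prediction to `s_i` (finite difference). The forgetting factor
(0.98) is applied per elapsed 15 min rather than per update — the
underlying parameter drifts in real time while sampling intervals vary
from 15 to 240 min — and the estimator variance is capped at 25× its
prior so that insulin-off periods (zero identifiability) cannot inflate
it. With forgetting 1 the recursion is algebraically ridge regression
with prior precision `1/P0`. The estimate is projected to ≥ 0.

*Rate selection.* Candidates are constant rates on a 0.5 IU/h grid from
0 to 50 IU/h, simulated (vectorised RK4, 5-min steps) over the longer
of the 120-min cost horizon and the largest sampling interval (240 min)
— the chosen rate may be held that long, so feasibility must cover it.
Selection is tiered:

1. among candidates predicted to stay ≥ 4.4 mmol/L (the range floor)
   everywhere, minimise `Σ_k (ĝ_k − 5.25)² + 0.01 (u − u_prev)²`
   (cost evaluated every 15 min over the horizon; ties go to the lower
   rate);
2. if none qualify, take the candidate with the greatest predicted
   minimum among those staying ≥ 3.5 mmol/L;
3. otherwise — or whenever the *current* glucose is below 3.5 mmol/L —
   insulin is 0.

The first tier is essential: with only the suspend threshold as a
constraint, the quadratic cost always selects descents that skim
3.5 mmol/L with zero margin, and any model error lands the real patient
below it. Treating the range floor as a hard constraint is standard
practice in clinical glucose MPC.

*Sampling interval.* The largest menu entry {15, 30, 60, 120, 180,
240} min for which the chosen candidate's prediction stays within
4.0–10.0 mmol/L; 15 min otherwise. The setpoint 5.25 mmol/L is the
midpoint of the 4.4–6.1 mmol/L target range.

The controller anticipates scheduled input changes: `recommend` accepts
the planned dextrose/carbohydrate trajectory, which the protocol
supplies, so the taper before the 18-h dextrose stop is predicted
rather than discovered. The controller contains no randomness.

## Protocol

Both arms: 24 h from ICU admission, insulin from 105 min (the CGM
run-in), dextrose for 18 h. Control arm: arterial samples at the
controller-computed intervals. CGM arm: the most recent valid 5-min
reading entered every 15 min; hourly checks (anchored at insulin start:
165, 225, …, 1425 min) draw an arterial reference, classify the pair on
the Clarke grid, and on C/D/E substitute the reference for the CGM
value and recalibrate. Any calibration resets the 12-h routine
calibration clock (initial calibration at 105 min, so an undisturbed
sensor is calibrated exactly twice, at 105 and 825 min). Checks
continue even in periods when a reference has just replaced the CGM
input. On sensor failure the trial continues with arterial sampling at
controller-computed intervals; failures are logged, never raised.
Arterial sampling is modelled as instantaneous, error-free plasma
glucose. Fault-injection hooks (a gain step, a forced failure time)
exist for robustness experiments and are off by default.

`run_cohort` is a paired design: the same synthetic cohort and the same
per-patient seeds under both arms, which removes between-patient
variance from the arm comparison. Seeding is hierarchical (one root
seed, split per component by name), so runs are bit-for-bit
reproducible and adding a component does not perturb the others.

## Endpoints

Metrics treat the trace as piecewise linear and find range crossings
analytically, making them sampling-resolution independent (a per-sample
counting mode exists for sensitivity checks). Percentages of time are
hours in stratum / 24 × 100; boundary values count as in range; time to
target is referenced to insulin start. A hypoglycemic episode starts
when glucose reaches 2.9 mmol/L and ends only after 30 contiguous
minutes at or above 3.9 mmol/L; shallower recoveries merge adjacent
excursions. The exit level and separation are conventions of this
package (configurable), chosen to avoid counting a single noisy
excursion twice.

## Problem sizes

The shipped experiments use 12 patients per arm for cohort runs, 20
patients for sensitivity-recovery checks, 1000 random traces for the
partition identity, a 202,500-point grid for the Clarke-zone
equivalence sweep, and 10,000 sensors for the failure-hazard check —
sizes chosen so the whole suite completes in well under a minute of CPU
while keeping Monte-Carlo standard errors far below the tested
tolerances.

## Known limitations

* No counter-regulatory response, meal absorption dynamics, renal
  glucose excretion, or drug interactions; the enteral route is a
  constant rate only.
* The arterial reference is error-free, so reference-side analytical
  error does not contribute to the Clarke-grid distribution.
* The controller's equivalence to any clinically deployed MPC is not
  claimed anywhere: cost, horizon and interval rule are this package's
  own design within the published input/output architecture.
* Simulated accuracy and endpoint values characterise this synthetic
  environment; they are not predictions of clinical performance.
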