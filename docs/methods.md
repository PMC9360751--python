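# Methods

## The decay model

Analyte levels in ventricular CSF after SAH are modelled multiplicatively:

```
y_it = exp(c_i) · exp(−λ·t) · exp(−δ·Q_it) · exp(ε_it)
```

with `t` days since SAH onset, `Q_it` the cumulative EVD drainage volume
(mL) at sampling time, `c_i` a patient-specific log starting level, and
`ε_it` mean-zero noise. After the log transformation this is a linear panel
model estimated by OLS with patient fixed effects. Two algebraically
identical routes are implemented — the within (demeaning) transformation
with degrees of freedom `n − N − k`, and explicit patient dummies via
statsmodels — and each serves as the oracle for the other in the tests.
p-values for λ and δ are conventional two-sided OLS t-tests; cluster-robust
errors are reserved for the logistic outcome models, where repeated
measurements per patient are the dominant dependence.

Decay is reported as percent per day, `100·(1 − e^(−λ))`, which is monotone
in λ and bounded above by 100. Back-extrapolation to bleeding onset is the
exact inverse of the decay, `value · e^(+λ·Δt)`.

Choices where the design was genuinely open:

* **Non-positive values** cannot enter a multiplicative model; they are
  excluded with a per-fit count, and an optional `offset` (+1) mode exists
  for zero-inflated late RBC counts. Default: exclusion.
* **Each analyte is fitted separately**; no joint fit across analytes.
* **All samples enter the fit**, including the rising limb of WBC/TP; the
  estimator deliberately projects the whole trajectory onto a single decay
  (see calibration below for why this is also how the generator is
  anchored). A post-peak-only analysis can be run by filtering the
  observation frame, but is not the default.
* **Drainage covariate**: cumulative daily totals up to and including the
  sampling day.

## Per-sample statistics

* Cell index `(CSF WBC × blood RBC)/(blood WBC × CSF RBC)`; undefined (an
  error, never zero) when CSF RBC is zero or no paired blood count exists.
* Fuchs-Rosenthal chamber counts are divided by 3 — the laboratory's "/3"
  reporting convention, not the 3.2 µL chamber geometry.
* Cytology: counts of granulocytes, lymphocytes, monocytes/macrophages and
  erythro-/siderophages in one visual field per slide quadrant; class means
  across the four quadrants are normalised to percentages summing to 100.
* Time points 1–6 bin days 1–4, 5–8, 9–11, 12–15, 16–18, 19–22; fractional
  days bin by floor; days beyond 22 fall outside the protocol.
* Total protein is treated as mg/dL by convention (`tp_unit` is a config
  field); no computation depends on the unit.

## The synthetic cohort generator

The generator emulates a single-centre serial-CSF study: 33 patients,
twice-weekly sampling over days 1–22, 177 samples in the reference layout.

**Schedule.** The default schedule is a deterministic fixture produced by a
closed-form rank rule: 18 patients with 6 visits, 10 with 5, 4 with 4 and
one with 3 (median 6, total 177), each visiting once per eligible time
point, with per-bin day counts arranged so the median sampling days are
exactly 3, 6, 10, 13, 17 and 20.5 and all gaps stay in the 3–5-day
twice-weekly range. A stochastic twice-weekly mode (`schedule="stochastic"`)
draws visit counts and gaps instead.

**Trajectories.** RBC follows `y0·e^(−λd)` with λ = −ln(1−0.281) ≈ 0.330,
i.e. the 28.1 %/day clearance reported for such cohorts, and y0 = 10⁶
cells/µL at onset. WBC and TP rise to a peak (days 6 and 13) before
falling; their log mean is a smoothed broken stick: asymptotic log-slope
`+rise` before the peak, `−fall` after, a logistic kink of width 1 day
positioned so the maximum sits exactly at the peak day, and the peak values
(2000 WBC/µL, 150 mg/dL TP) set the scale.

**Calibration.** A pure-decay fit applied to a rise-then-fall trajectory
estimates the within-patient least-squares projection of the log trajectory
on day — not the tail slope. The generator therefore solves for `fall` (by
Brent's method at configuration time) so that this projection, over the
reference schedule, equals the published decay parameter (0.2446/day WBC,
0.0651/day TP). A symmetric or gamma-shaped peak cannot do this for TP: any
shape whose log-derivative falls no faster than it rises projects to a
*positive* slope when the peak (day 13) lies beyond the mean sampling day
(11.5); a markedly steeper post-peak fall is a structural requirement of
jointly matching "peak at day 13" and "6.3 %/day fitted decay". The rise
rates (0.25/day WBC, 0.20/day TP) are not published quantities; they were
chosen so that, under the default noise, the observed per-patient maxima
concentrate at the published peak days. With the reference schedule's
available sampling days, the cohort median TP peak day settles at 12 (one
day before the nominal day-13 peak, within the one-day sampling resolution
of the protocol bins).

**Noise and effects.** Values are lognormal around the mean trajectory:
patient intercept sd τ = 0.6 and sample noise σ = 0.5 on the log scale
(order-of-magnitude spread typical of CSF counts; the source dispersion is
not numerically tabulated). Complication labels are drawn per patient
(prevalences 18% rebleeding, 15% ventriculitis, 36% DCI; onset days
lognormal matched to the reported median/IQR) from a dedicated RNG stream,
and their effects are constant multiplicative factors — rebleeding ×3 RBC
and ×1.5 TP plus a phagocyte shift in cytology delayed 4 days after onset;
ventriculitis ×3 WBC (hence ×3 cell index) plus a granulocyte shift; DCI
×2 RBC and ×2.5 WBC. Constant multipliers are absorbed by the patient
fixed effects, so decay estimates are unaffected by the complication mix.
Each patient's analyte draws and cytology draws use separate child streams
of the seed, so toggling effects or cytology never desynchronises the
remaining draws (the multiplicative-effect contract is exact and tested).

**Drainage.** Daily volume = patient rate × day factor, both lognormal:
the rate has median 199 mL/day with between-patient log-sd 0.308 (matching
the reported 159–241 IQR across patients) and the day-to-day factor log-sd
0.25. Between-patient rate heterogeneity matters: with a common rate,
cumulative drainage is nearly collinear with day within patient, which
inflates the variance of λ̂ severely when δ is co-estimated.

**Cytology.** Per quadrant, a Poisson(20) cell total is split multinomially
with day-dependent class weights (granulocyte mode near day 6; lymphocyte,
monocyte/macrophage and erythro-/siderophage modes near day 17).

**What the generator does not emulate.** No mechanistic CSF dynamics, no
missing-at-random laboratory dropout, no measurement censoring or rounding,
no correlation between analyte noises within a sample, no competing-risk
structure between complications, and real-data ROC operating points are not
targeted. Passing tests therefore demonstrate correctness of the estimators
under the stated statistical structure, not clinical performance.

## Inference calibration

The logistic outcome association clusters scores by patient, scales the
sandwich by G/(G−1) and refers the t-statistic to t(G−1). With a few dozen
clusters this family of corrections is known to remain slightly
anti-conservative; the test suite verifies the empirical type-I error on
500 null replicates against a 0.05 ± 2.58·MC-SE band. Complete or
quasi-separation (runaway coefficients, |β| > 50) is reported as
non-converged rather than as a spurious estimate.

## Numerical choices

* Within-estimator linear algebra is plain least squares on demeaned data;
  rank deficiency (e.g. drainage exactly proportional to day) raises an
  estimation error naming the collinear columns.
* Peak-day ties break to the earliest day; patients with fewer than two
  samples are excluded from peak-day statistics.
* Cutoff calls are strictly greater-than; a value at the cutoff is negative.
* AUC is delegated to scikit-learn's trapezoidal implementation and is
  cross-checked in the tests against an independent Mann–Whitney
  pair-counting oracle.
* When a patient contributes several samples to one time-point bin, the
  within-bin mean represents the patient in summaries and contrasts.
* Significance level 5% throughout, no multiplicity correction by default
  (a Holm adjustment can be applied downstream by users).
* The fall-rate calibration solves on (10⁻⁶, 20) with Brent's method to
  machine tolerance; calibration always targets the reference schedule's
  day distribution, including when cohorts are later generated with the
  stochastic schedule.

## Known limitations

* The decay model is deliberately misspecified for peaked analytes (it is a
  projection); its λ is an average clearance over the observation window.
* δ (drainage decay) is identified mainly through between-patient rate
  differences interacting with time; with 33 patients its power is low —
  consistent with the original null finding it emulates.
* Real sensitivities/specificities at the clinical cutoffs (cell index > 2,
  WBC > 1000) depend on cohort specifics the generator does not target;
  the package evaluates them but their values on synthetic cohorts are not
  comparable to published ones.
* The generator's trajectories are phenomenological; parameter recovery
  results say nothing about mechanistic interpretability of λ.
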