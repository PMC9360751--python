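# csfdecay

Longitudinal analytics for ventricular cerebrospinal fluid (CSF) after
spontaneous subarachnoid hemorrhage (SAH).

Patients with severe SAH often need an external ventricular drain (EVD), and
the CSF drawn through it — typically twice weekly — is the main window onto
complications such as rebleeding, drain-associated ventriculitis and delayed
cerebral ischemia (DCI). Interpreting a single CSF value is hard because red
cells, white cells and total protein all follow strong, analyte-specific time
courses after the bleed. This package provides, for clinical researchers and
biostatisticians working with serial CSF data:

* a **decay-model estimator** for the in-vivo clearance of CSF analytes,
* **cell-index and cytology statistics** with protocol time-point binning,
* **group contrasts and outcome associations** honouring repeated sampling,
* **fixed-cutoff / ROC prediction** of later complications from the first
  CSF collection, and
* a **seeded synthetic cohort generator** that emulates such a study
  end-to-end, so every stage is testable without patient data.

## The model

The level of analyte *y* (RBC/µL, WBC/µL or total protein) in patient *i* at
*t* days after SAH onset is modelled as exponential decay in time and in the
cumulative CSF volume drained via the EVD, *Q<sub>it</sub>* (mL):

```
ln(y_it) = c_i − λ·t − δ·Q_it + ε_it
```

estimated by OLS with one intercept per patient (fixed effects). The decay
rate is reported as a percentage per day, `100·(1 − e^(−λ))`, and can be
inverted to back-extrapolate a measured count to the time of the bleed
(`value·e^(+λ·Δt)`), e.g. when judging a delayed lumbar puncture.

Per-sample statistics follow routine laboratory conventions: the cell index
`(CSF WBC × blood RBC) / (blood WBC × CSF RBC)` corrects CSF pleocytosis for
blood admixture; Fuchs-Rosenthal chamber counts are reported "/3"; cytology
proportions are quadrant means normalised to 100%. Samples are grouped into
six protocol time points (days 1–4, 5–8, 9–11, 12–15, 16–18, 19–22).
Outcome associations use logistic regression with patient-clustered sandwich
errors (G/(G−1) scaling, t(G−1) p-values).

## Worked example

```python
from csfdecay import (default_config, generate_cohort, fit_decay,
                      DecayModelSpec, peak_day, back_extrapolate)

cohort = generate_cohort(default_config(), seed=1)   # 33 patients, 177 samples
for analyte in ("rbc", "wbc", "tp"):
    fit = fit_decay(DecayModelSpec.from_cohort(cohort, analyte))
    print(f"{analyte}: lambda={fit.lambda_hat:.3f} "
          f"({fit.percent_per_day:.1f}% per day), p={fit.lambda_p:.2e}")
print("WBC peak day:", peak_day(cohort, "wbc"))
print("RBC at onset from 719/uL one day later:",
      round(back_extrapolate(719.0, 1.0, 0.330)))
```

prints (this exact seed):

```
rbc: lambda=0.333 (28.3% per day), p=1.63e-27
wbc: lambda=0.256 (22.6% per day), p=1.92e-09
tp: lambda=0.032 (3.1% per day), p=6.49e-01
WBC peak day: 6.0
RBC at onset from 719/uL one day later: 1000
```

Red cells clear fastest (about 28% per day), white cells similarly (the
single-cohort estimate scatters around 22% per day), total protein far more
slowly — a single 177-sample cohort estimates the small TP decay noisily
(here 3.1% per day, not significant), which is why the replication studies
below average over many cohorts. The back-extrapolation inverts a one-day
28.1% decline (719 → 1000 cells/µL).

The same stages are scriptable from a shell:

```bash
csfdecay generate --out data --seed 1
csfdecay fit-decay --input data/samples.csv --analyte rbc --out fit.json
csfdecay run --outdir results --seed 1     # full bundle, all stages
```

## Layout

| module | contents |
|---|---|
| `csfdecay.domain` | record types, cell index, chamber convention, cytology proportions, time-point bins |
| `csfdecay.io` | samples.csv / patients.csv dialects, tidy analysis frames |
| `csfdecay.synthetic` | generator config, reference schedule fixture, trajectory calibration, cohort generation |
| `csfdecay.decay` | fixed-effects decay fit (within & dummy routes), percent-per-day, back-extrapolation |
| `csfdecay.cohort_stats` | time-point summaries, peak days, group contrasts, clustered logistic associations |
| `csfdecay.roc` | first-collection predictors, fixed cutoffs, AUC |
| `csfdecay.pipeline` / `csfdecay.cli` | end-to-end bundles, provenance, `csfdecay` command |

See `docs/methods.md` for modelling assumptions, calibration details and
known limitations.
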