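# firstdose

Target-attainment analysis for the **first dosing interval** of
extended-infusion beta-lactam therapy (meropenem, piperacillin) in
critically ill adults — for clinical pharmacologists, pharmacometricians
and intensivists studying early antibiotic exposure.

Standard ICU regimens start with a 0.5 h loading infusion immediately
followed by a 3 h extended infusion, repeated every τ hours. Because
beta-lactam killing is time-dependent, the question is whether the free
(unbound) concentration stays above the pathogen MIC for the whole
interval — *100% fT>MIC* — from the very first dose, and how renal
function (especially augmented renal clearance, ARC) drives failures.

The package provides, end to end:

- **Two-compartment infusion PK**: exact closed-form concentration–time
  profiles under arbitrary piecewise constant-rate infusion schedules
  (CL, V1, Q, V2; C(t) = Σ events R·[A/α(1−e^{−αs})e^{−αw} + B/β(…)]).
- **MAP Bayesian (empirical Bayes) estimation**: individual parameters as
  the mode of p(η|y) ∝ Π N(y_j | f(t_j;η), (a+b·f)²) · N(η|0,Ω) from
  three sparse samples (post-loading Cmax, end of infusion, trough), with
  a seeded Metropolis–Hastings mode search as an independent cross-check.
- **Exposure endpoints**: binding-adjusted total thresholds
  (multiplier·MIC/fu; piperacillin 16 mg/L free → 20 mg/L total),
  %fT>MIC over the first interval and first 24 h with root-refined
  crossing times, predicted troughs at the exact interval end,
  dose-normalized Cmin/Cmax ratios, terminal half-lives (ln 2/β).
- **Renal function**: CKD-EPI 2021 eGFR, Du Bois BSA, absolute eGFR,
  Cockcroft–Gault CrCL, the ARC risk score (age/trauma/SOFA), the
  suspected-ARC rule (CrCL > 130, or > 90 with score > 6), KDIGO AKI.
- **Cohort statistics**: exact Wilcoxon rank-sum tests with
  Hodges–Lehmann shift CIs, Youden-optimal ROC cutoffs on the Cmin/Cmax
  ratio versus ARC status, ECDF (cumulative distribution) analyses,
  per-drug summary tables.
- **A synthetic ICU cohort generator** reproducing the covariate
  distributions, regimen mix, three-sample schedule, timing jitter and
  residual noise of a first-dose TDM study, with full ground truth for
  validation.

## Worked example

```python
from firstdose import *
from firstdose.io import load_default_models

pop = load_default_models()["meropenem"]

# a young trauma patient with augmented renal clearance
cov = PatientCovariates("P001", age=45, sex="male", weight=80, height=180,
                        serum_creatinine=55, sofa=3, trauma_admission=True)
ra = assess_renal_function(cov)

regimen = DosingRegimen("meropenem", InfusionEvent(0, 0.5, 1000), 1000, tau=8)
obs = ObservationSet((
    Observation(0.5, 52.0, "post_loading_cmax"),
    Observation(3.4, 14.0, "end_infusion"),
    Observation(8.3, 1.6, "trough"),      # drawn 12 min early
))
fit = map_fit(obs, pop, cov=cov, crcl=ra.crcl, regimen=regimen)
summ = exposure_summary(fit.individual, regimen, DEFAULT_TARGETS["meropenem"], obs=obs)
```

This prints (via the obvious f-strings):

```
CrCL 170 mL/min, eGFR 120, ARC score 10, suspected ARC: True
individual CL 19.2 L/h, V1 14.8 L (converged: True)
predicted Cmin 1.27 mg/L, fT>MIC first interval 87.4%, first 24h 82.0%
100% fT>MIC attained: False, Cmin/Cmax ratio 0.031, terminal half-life 1.62 h
```

Reading: Cockcroft–Gault CrCL of 170 mL/min with a maximal ARC score
flags suspected ARC. The fitted individual clearance (19.2 L/h) is well
above typical; the model-predicted trough at the exact end of the 8.5 h
interval (1.27 mg/L) is below the 2 mg/L meropenem target, so despite
87% fT>MIC the patient misses the 100% target — and the steep
peak-to-trough decline (Cmin/Cmax 0.031, i.e. a >30-fold drop) is exactly
the ratio signature associated with ARC.

The same pipeline runs from the shell:

```
firstdose run --n-meropenem 22 --n-piperacillin 48 --seed 1 --out results/
firstdose generate --n-piperacillin 100 --seed 7 --out cohort/
```

writing `exposure.csv`, `cohort_summary.csv`, `comparisons.csv`, `roc.csv`
and a run log (every file header carries the seed and a config hash; a
re-run with the same settings is bit-identical).

## Layout

```
src/firstdose/
  renal.py      eGFR / CrCL / ARC / KDIGO
  pk.py         regimens, two-compartment engine, population models (+ models/*.yaml)
  estimate.py   MAP and Metropolis–Hastings conditional modes
  exposure.py   thresholds, fT>MIC, troughs, ratios, half-lives
  stats.py      exact Wilcoxon, ROC/Youden, ECDFs, cohort tables
  cohort.py     synthetic ICU cohort generator
  io.py, cli.py CSV/NONMEM I/O, pipeline, command line
docs/methods.md model, conventions, design choices, limitations
```
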