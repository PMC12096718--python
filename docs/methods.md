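# Methods

`firstdose` analyses plasma target attainment during the *first dosing
interval* of extended-infusion beta-lactam therapy (meropenem,
piperacillin) in critically ill adults. The regimen of interest is a 0.5 h
loading infusion immediately followed by a 3 h extended infusion, repeated
every τ hours; the question is how often the free drug concentration stays
above the MIC for the whole first interval, and how renal function —
especially augmented renal clearance (ARC) — drives failures.

## Structural PK model

Both drugs follow a two-compartment disposition model parameterized by
clearance CL (L/h), central volume V1 (L), inter-compartmental clearance Q
(L/h) and peripheral volume V2 (L), with micro-constants k10 = CL/V1,
k12 = Q/V1, k21 = Q/V2. Dosing is a sequence of constant-rate infusions
into the central compartment. Because the kinetics are linear, the
concentration at any time is the superposition over infusion events of the
closed-form biexponential infusion solution

C(t) = R · [A/α (1 − e^{−αs}) e^{−αw} + B/β (1 − e^{−βs}) e^{−βw}],

where R is the infusion rate, s the infused time, w the washout time
since infusion end, α > β the hybrid rate constants (roots of
λ² − (k10+k12+k21)λ + k10·k21 = 0), and A, B the unit-bolus coefficients.
Q = 0 reduces exactly to one-compartment kinetics (handled as a separate
branch). The closed form is the only evaluation path; numerical ODE
integration exists solely as an independent test oracle, and the two agree
to better than 1e−9 relative error in practice (contract: 1e−6).

The maintenance clock is anchored at the end of the loading infusion: the
k-th extended infusion starts at 0.5 + k·τ, and the "first dosing
interval" is [0, 0.5 + τ]. This matches a protocol in which the extended
infusion starts immediately when the loading infusion ends.

## Population model and individual estimation

Individual parameters are log-normally distributed around covariate-
adjusted typical values: Pᵢ = θ_P · m_P(covariates) · exp(η_P), with
η ~ N(0, diag(ω²)) and covariate multipliers of power
((x/ref)^coef) or proportional (1 + coef·(x − ref)) form. The meropenem
model carries creatinine clearance and age effects on CL and body weight
on V1; the piperacillin model has no covariates. Residual error is
combined: SD(y|f) = a + b·f.

Typical values, omegas, covariate coefficients and error coefficients live
in editable YAML files (`firstdose/models/*.yaml`). The shipped defaults
are literature-informed representative values for critically ill adults,
chosen once so that simulated concentration magnitudes match what is
observed with these regimens (meropenem: median Cmax ≈ 55–60 mg/L after a
1–2 g loading dose, median q8h trough ≈ 2–3 mg/L; piperacillin: median
Cmax ≈ 230 mg/L after 4 g, median q6h trough ≈ 25–30 mg/L). Every test is
parameter-agnostic: swapping the YAML values changes no test logic.

Given a patient's sparse observations y (three samples), the individual
random effects are estimated as the mode of the conditional distribution
p(η|y) ∝ Π N(y_j | f(t_j; η), g(f)²) · N(η | 0, Ω) — the empirical Bayes
estimate. The primary estimator (`map_fit`) maximizes the log-posterior
deterministically (BFGS polished by Nelder–Mead, multi-start from 0 and
±1 prior SD). A seeded random-walk Metropolis–Hastings mode search
(`conditional_mode_mh`) targets the same density and serves as an
independent cross-check; the two agree in −2·log-posterior within 0.1 on
synthetic patients. Observations below the 0.1 mg/L quantification limit
are excluded with a logged warning (censored-likelihood handling is out of
scope; BLQ values are not expected at these doses). Recorded actual
sampling times, not nominal protocol times, enter the likelihood —
mistimed troughs are the rule in practice and the motivation for
model-predicted troughs.

Shrinkage behaviour is as expected for empirical Bayes: growing the
residual error pulls the mode monotonically toward η = 0 (tested on a pure
variance scale, i.e. additive error only; scaling the *proportional*
coefficient also reweights observations by their predictions and need not
shrink monotonically).

## Exposure endpoints

Targets are free-drug MICs (EUCAST P. aeruginosa cut-offs: meropenem
2 mg/L, piperacillin 16 mg/L). Measured concentrations are total, so
comparisons are made on the total scale against the binding-adjusted
threshold multiplier·MIC/fu, with fu = 1.0 for meropenem and 0.8 for
piperacillin (total piperacillin target 20 mg/L). Under constant binding
this is mathematically identical to comparing unbound concentration to the
free target. Attainment is strict: a trough exactly at the threshold does
not attain.

%fT>MIC is the fraction of a window during which C(t) exceeds the
threshold, with crossing times refined by bracketing plus Brent root
finding (≈1e−10 h, contract 1e−4 h). One convention matters: the
concentration starts at zero, so the very first administration necessarily
spends a short ramp-up below any positive threshold. Counting that ramp
would make 100% fT>MIC unattainable by construction for the first
interval. The window is therefore clocked from the first up-crossing of
the threshold, which makes "100% fT>MIC over the first interval" exactly
equivalent to "predicted trough above the threshold" — the equivalence the
attainment definition relies on. A profile that never reaches the
threshold scores 0%. The 24 h window assumes the maintenance regimen
continues unchanged through 24 h.

Terminal half-life is ln 2/β by default, with a log-linear regression
estimate on the simulated washout tail as a cross-check (the regression
window must sit deep in the terminal phase to avoid α-phase
contamination). The Cmin/Cmax ratio — the peak-to-trough decline over the
first interval — normalizes Cmax by the loading amount and Cmin by the
maintenance amount to a standard dose (1 g meropenem, 4 g piperacillin),
since each sample reflects the most recent infusion. Piperacillin patients
on intervals longer than 6 h contribute the model-predicted concentration
6 h after the start of the extended infusion as Cmin, keeping ratios
comparable with q6h patients.

## Cohort statistics

Two-group comparisons use the Wilcoxon rank-sum test: exact null
distribution for combined n ≤ 25 (tie-free), tie-corrected normal
approximation above, plus the Hodges–Lehmann shift estimate (median of
pairwise differences) with the exact-inversion 95% confidence interval
(order statistics of the pairwise differences at the exact Mann–Whitney
critical value, computed by the standard counting recursion).

ROC analysis seeks the Cmin/Cmax cutoff separating suspected-ARC from
non-ARC patients, where "positive" means a ratio *below* the cutoff (steep
decline ⇒ augmented clearance). Candidate cutoffs are midpoints between
adjacent sorted unique ratios; the optimum maximizes Youden's
J = sensitivity + specificity − 1, with ties broken toward higher
specificity and then the smaller cutoff (the optimality criterion and tie
rules are this package's explicit choices). The cumulative-distribution
analysis computes per-group ECDFs on the same candidate grid; its
maximum-vertical-separation cutoff coincides with the Youden cutoff by
construction.

## Renal function

Relative eGFR uses the race-free CKD-EPI 2021 creatinine equation
(creatinine stored in µmol/L, converted at 88.42 µmol/L per mg/dL);
absolute eGFR de-indexes by Du Bois BSA/1.73. Creatinine clearance uses
Cockcroft–Gault with actual body weight, kept absolute (not
BSA-normalized). The ARC risk score allocates 6 points for age ≤ 50
years, 3 for trauma admission, 1 for SOFA ≤ 4 (configurable table);
ARC is CrCL > 130 mL/min, and "suspected ARC" is CrCL > 130, or
CrCL > 90 with a score > 6. The eGFR grouping boundary is 90
mL/min/1.73 m² (groups ">90" and "≤90"). KDIGO AKI screening flags a
creatinine rise ≥ 26.5 µmol/L within 48 h, a rise to ≥ 1.5× baseline
within 7 days, or urine output ≤ 0.5 mL/kg/h sustained ≥ 6 h; the
baseline defaults to the earliest available value when not supplied.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested. Covariate anchors are the study population's medians/IQRs per drug
arm (e.g. meropenem: age 58 (46–69) y, weight 83 (68–94) kg, creatinine
58 (46–78) µmol/L, 73% male, 41% trauma). Skewed positive covariates
(weight, creatinine) are log-normal; age and height are truncated normal;
IQR width maps to scale via 1.349·SD on the relevant scale. Covariates are
drawn independently (the joint correlations are unreported), except that
the implied Cockcroft–Gault CrCL is internally consistent with the
anchors (median ≈ 144 mL/min in the meropenem arm).

The regimen mix matches the observed mix (meropenem: 1+1 g q8h 50%,
2+2 g 27%, 1+2 g 14%, 0.5+1 g 9%, all q8h; piperacillin: 4+4 g q6h 71%,
q8h 19%, with the heterogeneous 10% "other" category concretized as
2+2 g q6h 6% and 4+4 g q12h 4%). Sampling follows the three-sample
protocol: end of loading (0.5 h), uniform in the last 15 min of the
extended infusion ([3.25, 3.5] h), and a trough at the interval end with
normal timing jitter (SD 0.25 h, truncated at ±1 h — the observed extreme
band; this puts ≈95% of troughs within ±0.5 h, consistent with the
observed 82%). Noise follows the model's combined error,
y = f(1 + b·ε₂) + a·ε₁, resampled on non-positive draws, with values
below 0.1 mg/L flagged BLQ.

Because the piperacillin model has no renal covariate, ARC enrichment
would otherwise not propagate into clearance; the generator therefore
correlates η_CL with the cohort's CrCL normal scores (Gaussian copula,
default rank correlation 0.6) for covariate-free models. An optional
`arc_fraction` resamples that fraction of patients from a younger,
low-creatinine, trauma-heavy anchor set to enrich suspected ARC.

What the generator does *not* emulate: covariate correlations (weight ×
height, etc.), time-varying renal function within the interval,
non-plasma matrices, assay error structure beyond the combined model, or
dose adjustments after the first interval. Passing tests therefore show
internal consistency of the pipeline under the stated model, not external
validity on real patients.

## Problem sizes and numerical choices

Default problem sizes were chosen to exercise each guarantee convincingly
while keeping the full suite and the acceptance script comfortably fast:
100 random parameter/regimen draws for the ODE contract, 200 simulated
patients (100 per drug) for parameter recovery, 100/500 patients for the
crossing and trough-equivalence checks, exhaustive enumeration up to
combined n = 8 for the exact test, 50 datasets for the ROC oracle, a
170-patient ARC-enriched cohort for the qualitative findings, and a
70-patient (22 + 48) cohort for the end-to-end determinism run. Profile
grids always contain the infusion knots exactly; fT>MIC scanning uses a
0.02 h grid before root refinement; the MAP optimizer uses gradient
tolerance 1e−8 with a derivative-free polish; all randomness flows from
explicit seeds, and a fixed seed reproduces every output bit-for-bit.

## Known limitations

- Model parameter defaults are representative, not estimated from data;
  all downstream percentages (attainment rates, cutoffs) depend on them.
- BLQ observations are excluded rather than treated by censored
  likelihood.
- The MH mode search is a cross-check, not a posterior sampler; no
  uncertainty intervals on individual parameters are produced.
- Population-parameter estimation (SAEM/FOCE), three-compartment models,
  tazobactam, renal-replacement therapy and mortality modelling are out of
  scope.
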