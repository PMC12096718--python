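# Population PK model for meropenem in critically ill adults.
#
# Two-compartment model with creatinine clearance and age as covariates on
# clearance and body weight on the central volume. Numeric values are
# editable, literature-informed representative estimates for this population
# (typical CL ~12-13 L/h at CrCL 100 mL/min, Vss ~25-30 L, terminal
# half-life ~1-2.5 h); they reproduce the observed concentration magnitudes
# of extended-infusion regimens (median Cmax ~57 mg/L after a 1-2 g loading
# dose, median Cmin ~2.7 mg/L q8h). Between-subject variability is
# log-normal; residual error is combined (a + b*f).
drug: meropenem
typical:
  CL: 12.6     # L/h at the reference covariates
  V1: 17.5     # L at 70 kg
  Q: 15.0      # L/h
  V2: 12.0     # L
covariate_effects:
  - parameter: CL
    covariate: crcl
    form: power
    coefficient: 0.62
    reference: 100.0     # mL/min
  - parameter: CL
    covariate: age
    form: power
    coefficient: -0.25
    reference: 55.0      # years
  - parameter: V1
    covariate: weight
    form: power
    coefficient: 1.0
    reference: 70.0      # kg
omega:
  CL: 0.30
  V1: 0.25
  Q: 0.30
  V2: 0.30
error:
  additive_a: 0.20       # mg/L
  proportional_b: 0.15
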