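# Population PK model for piperacillin in critically ill adults.
#
# Two-compartment model without covariates, developed in an ICU population.
# Numeric values are editable, literature-informed representative estimates
# (typical CL ~14 L/h, Vss ~25 L, terminal half-life ~1.5-2.5 h); they
# reproduce the observed concentration magnitudes of extended-infusion
# regimens (median Cmax ~230 mg/L after a 4 g / 0.5 h loading dose, median
# Cmin ~29 mg/L q6h). Between-subject variability is log-normal; residual
# error is combined (a + b*f).
drug: piperacillin
typical:
  CL: 14.0     # L/h
  V1: 14.0     # L
  Q: 10.0      # L/h
  V2: 11.0     # L
covariate_effects: []
omega:
  CL: 0.40
  V1: 0.35
  Q: 0.30
  V2: 0.30
error:
  additive_a: 1.0        # mg/L
  proportional_b: 0.15
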