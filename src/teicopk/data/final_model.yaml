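# Final population model for teicoplanin in adult septic patients.
# CL is scaled by renal function: CL_i = 1.03 * (GFR_i / 71.88)^0.437 * exp(eta_CL).
# omega2 are variances of the log-normal inter-individual random effects;
# sigma2_prop is the variance of the proportional residual (SD 17.4%).
name: teicoplanin-sepsis-final
typical_values:
  CL: 1.03    # L/h at the reference GFR of 71.88 mL/min/1.73 m^2
  V1: 20.1    # L
  Q: 3.12     # L/h
  V2: 101.0   # L
covariate_effects:
  - parameter: CL
    covariate: GFR
    form: power
    beta: 0.437
    reference: 71.88
omega2:
  CL: 0.29
  V1: 0.37
  Q: 0.29
  V2: 0.10
sigma2_prop: 0.030276   # 0.174^2
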