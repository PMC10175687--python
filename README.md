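# teicopk

Population pharmacokinetics and dosing-regimen optimization of **teicoplanin
in critically ill septic patients**.

Teicoplanin is a glycopeptide antibiotic used against MRSA and other
resistant gram-positive organisms. It is ~90% protein bound, renally
cleared, and has a terminal half-life of roughly 100 h, so patients need
intensified loading doses and carefully chosen maintenance intervals —
especially in sepsis, where distribution volumes grow and renal function
varies from failure to augmented clearance. `teicopk` implements the full
model-based workflow for this problem, for pharmacometricians and
infectious-disease researchers:

* a **two-compartment intravenous-infusion model** in closed form
  (parameters CL, V1, Q, V2; micro constants k10 = CL/V1, k12 = Q/V1,
  k21 = Q/V2), with exact multi-dose superposition and analytic or
  linear-trapezoidal AUC;
* a **population layer**: typical values scaled by renal function through a
  power model, CL_i = CL_pop · (GFR_i / 71.88)^0.437 · e^{η_i},
  log-normal inter-individual variability η ~ N(0, ω²) per parameter, and
  proportional residual error C_obs = C_pred (1 + ε), ε ~ N(0, σ²_prop).
  The published final model (CL 1.03 L/h, V1 20.1 L, Q 3.12 L/h, V2 101 L;
  ω² = 0.29/0.37/0.29/0.10; σ_prop = 17.4%) ships as the default preset;
* a **synthetic-cohort generator** reproducing the study design: 59 septic
  ICU patients stratified over five renal-function classes, the standard
  400 mg q12h×3 → q24h regimen, and sparse TDM sampling (troughs before
  doses 3–6 plus one extra sample assigned in thirds);
* **nonlinear mixed-effects estimation**: Laplace-approximate marginal
  likelihood (OFV = −2 log L) with the η–ε interaction, quasi-Newton
  population fits, stepwise covariate selection (forward ΔOFV > 3.84,
  backward ΔOFV > 10.828), subject-level bootstrap, CWRES goodness-of-fit
  residuals, and a prediction-corrected visual predictive check;
* **Monte Carlo dosing simulation**: per-regimen medians and 95% prediction
  intervals of the Day-4 trough (C_min,72h), the near-steady-state trough
  (C_min,240h) and the daily AUC over the final maintenance interval;
* **PK/PD evaluation**: PTA for AUC_0–24/MIC ≥ 610 over the MIC grid
  {0.25, 0.5, 1, 2, 4} mg/L, CFR = Σ PTA(MIC_i)·p(MIC_i) against an
  editable MRSA MIC histogram, and regimen classification against the
  15–30 mg/L (non-complicated) / 20–40 mg/L (complicated) trough bands.

## Worked example

```python
import numpy as np
from teicopk import final_model, recommend_regimen, simulate_regimen, pta_profile, cfr
from teicopk.pkpd import default_mic_distribution

model = final_model()                      # the published population model
spec = recommend_regimen(gfr=45.0)         # 15 mg/kg q12h x3, daily d2-3, then q48h
met = simulate_regimen(model, 45.0, spec, 1000, np.random.default_rng(11))
print(round(float(np.median(met.cmin_72h)), 2), round(float(np.median(met.auc_24h)), 1))
profile = pta_profile(met.auc_24h)
print(profile[1.0], round(cfr(profile, default_mic_distribution()), 3))
```

prints (seed 11):

```
17.01 670.7
0.606 0.818
```

i.e. the moderate-renal-impairment regimen achieves a median Day-4 trough of
~17 mg/L (inside the 15–30 mg/L therapeutic band) and a median daily
AUC/MIC of ~671 at MIC 1 (above the 610 efficacy target), but only 61% of
simulated patients attain the target at MIC 1 mg/L; the
distribution-weighted CFR of ~0.82 sits in the 80–90% "moderate probability
of success" band — adequate exposure for susceptible isolates, thinner
cover for empirical MRSA therapy.

Runnable walkthroughs live in `examples/` (concentration profiles, the
dosing table, a synthetic-cohort fit, PTA/CFR, model validation). A thin
CLI mirrors the pipeline: `teicopk simulate-cohort | fit | covariate-step |
bootstrap | vpc | simulate-dosing | pta-cfr | recommend`.

## Layout

| module        | contents                                              |
|---------------|-------------------------------------------------------|
| `teicopk.pk`          | closed-form two-compartment infusion kinetics |
| `teicopk.population`  | typical values, covariates, IIV, residual     |
| `teicopk.regimen`     | dosing-table regimens → infusion events       |
| `teicopk.cohort`      | synthetic study cohorts (sparse TDM design)   |
| `teicopk.estimation`  | Laplace fits, covariate step, bootstrap, VPC  |
| `teicopk.montecarlo`  | regimen-level exposure simulation             |
| `teicopk.pkpd`        | PTA, CFR, regimen classification              |
| `teicopk.dataio`      | NONMEM-style rectangular CSV round-trip       |
| `teicopk.cli`         | command-line pipeline                         |

See `docs/methods.md` for the model, numerical methods, and the design
choices behind the synthetic data and the estimator.
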