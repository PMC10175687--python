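# Methods

This note documents the models, numerical methods and design choices behind
`teicopk`. It is written for a reader who wants to know exactly what the
package computes and where its synthetic experiments do — and do not —
speak for real data.

## Structural model

Teicoplanin disposition is described by a two-compartment model with
zero-order intravenous infusion input and first-order elimination from the
central compartment. Parameters are clearance CL (L/h), central volume V1
(L), intercompartmental clearance Q (L/h) and peripheral volume V2 (L);
micro constants are k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, and the hybrid
disposition constants α > β > 0 are the roots of
s² − (k10+k12+k21)s + k10·k21. With the published parameters the terminal
half-life ln2/β is ≈101 h, inside the label's 100–170 h range.

The central concentration is evaluated in closed form: a single infusion of
rate R₀ contributes, per hybrid phase x ∈ {α, β} with bolus coefficients
A = (α−k21)/(α−β), B = (k21−β)/(α−β),

    C(τ) = (R₀/V1) Σₓ (Xₓ/x) (1 − e^{−x·min(τ,T)}) e^{−x·max(τ−T,0)}

and multi-dose profiles are exact superpositions. An infusion contributes
zero at its own start time, so evaluating at a dose time gives the pre-dose
trough — the convention used for all reported C_min values. The AUC has the
matching closed form (antiderivative per phase); the linear trapezoidal
rule on a 0.1 h grid is provided as an alternative and agrees with the
analytic integral to <0.2% (verified in tests). The closed form is checked
against stiff ODE integration of the mass-balance system to ≤1e-6 relative
error on randomized parameter/schedule cases.

The kernel is JIT-compiled with numba when available (a pure-numpy path
gives identical results to machine precision and is the fallback); this
matters because the estimator evaluates the model millions of times.

## Population model

Individual parameters are log-normal around covariate-adjusted typical
values: P_i = P_TV(cov_i)·e^{η_i}, η_i ~ N(0, ω²) independently per
parameter (no covariance block — none is reported for this drug).
Continuous covariates enter as power laws, P_TV = P_pop·(COV/COV_ref)^β;
binary covariates as P_pop·e^{β·COV}. The shipped final model has one
effect: CL scaled by (GFR/71.88)^0.437. Reported percent CVs are
interpreted as √ω²·100 (0.29 → 53.9%), which makes the published table and
equations mutually consistent. Residual error is proportional,
C_obs = C_pred(1+ε), ε ~ N(0, σ²_prop) with σ_prop = 17.4%. Negative
residual draws are truncated to zero only when writing synthetic
observation files, never inside estimation math, so the generative model
stays exactly the stated one.

## Synthetic cohorts

The generator emulates the source study's conditions: 59 septic ICU
patients; GFR drawn from five renal-function strata with probabilities
(0.237, 0.339, 0.237, 0.085, 0.102) and uniform within stratum bounds
(top stratum 90–124, bottom 11–15 mL/min/1.73 m²); weight log-normal with
median 65 kg and log-SD 0.18, truncated to 35–90 kg (the log-SD is chosen
so the truncation bounds sit near ±2.5 SD — the study reports only median
and range); age discrete-uniform 28–92 y; 62.7% male. A panel of
distractor laboratory covariates (ALT, AST, bilirubins, proteins, WBC,
creatinine, BUN, height/BMI) is sampled independently within the reported
ranges purely to exercise covariate screening; their joint distribution is
deliberately unrealistic (independent), so screening experiments test
rejection of noise, not real collinearity.

Dosing follows the standard regimen (400 mg q12h ×3 then 400 mg q24h);
sampling is the study's sparse TDM design: troughs immediately before the
3rd–6th doses (24, 48, 72, 96 h) plus one extra sample assigned cyclically
in thirds — end of the 5th infusion, 1 h after the start of the 5th
infusion (start-anchored, the usual TDM reading of "1 h after the dose"),
or 1 h before the 6th dose. With the default 1 h infusions the first two
arms coincide at 73 h; they remain distinct settings under other durations.
Observations are independently thinned at rate 0.156, calibrated so a
59-subject cohort keeps ≈249 of its 295 scheduled samples, matching the
study's count; values below the assay quantification limit (3.125 mg/L)
are flagged.

## Estimation

The marginal likelihood of each subject's data is approximated by the
Laplace method. Writing g(η) for the negative joint log density (data
likelihood with variance σ²·f(η)² evaluated at the conditional prediction —
the η–ε interaction — plus the Gaussian prior), the subject's contribution
to the objective function value is

    OFV_i = 2·g(η̂_i) + log|H_i| − q·log 2π,

with η̂_i the conditional mode (the empirical-Bayes estimate), H_i the
Hessian of g at the mode, and q the number of random effects. With all ω²
at zero this reduces exactly to the fixed-effects weighted-least-squares
deviance. On one-subject, one-random-effect problems the approximation
agrees with adaptive Gauss–Hermite quadrature to <0.1 OFV units (tested).

Numerics, in order of importance:

* **Conditional modes.** All (model, subject) pairs are solved as one
  batched problem — including the finite-difference stencil over population
  parameters used for the outer gradient, so one objective-plus-gradient
  evaluation is a single batched solve. The search is damped Gauss–Newton
  with the analytic objective gradient and J'WJ+Ω⁻¹ curvature (W uses the
  exact second derivative of the per-observation deviance, including the
  log-variance term), followed by full finite-difference Newton on rows the
  GN phase leaves unconverged. Rows are independent, so converged rows drop
  out of the working set exactly. Steps are norm-clipped at 2 log-units to
  prevent overflow excursions.
* **Outer optimization.** L-BFGS-B over log-transformed typical values and
  variances (covariate coefficients on the natural scale), with bounds
  (log TV ∈ [log 1e-3, log 1e4], β ∈ [−10, 10], ω² ≤ 25, σ² ≤ 4). The
  objective is capped at 1e8: un-capped pathological values (~1e14 from the
  variance floor) destroy the line-search interpolation. Modes are solved
  to a loose 2e-4 gradient tolerance inside the search (the OFV error from
  an imperfect mode is second-order) and re-solved to 1e-6 for the reported
  OFV, which is therefore a deterministic, comparable quantity across fits.
  Each fit restarts L-BFGS-B from its own optimum until the gain drops
  below 0.01 units (resets the quasi-Newton memory, which reliably escapes
  premature flat-valley terminations), and optionally multi-starts from
  jittered initials on non-convergence, returning the best iterate flagged
  by a convergence status.
* **Covariate screening.** Stepwise, one effect at a time: forward
  inclusion while the best OFV drop exceeds 3.84 (χ², P=0.05), then
  backward deletion keeping effects whose removal costs more than 10.828
  (P=0.001); every tested ΔOFV lands in an audit table. Candidate
  coefficients are initialized from the least-squares slope of the
  empirical-Bayes η̂ against the (log) covariate — the OFV profile in a new
  coefficient can be multimodal, and quasi-Newton search from zero stalls
  on real cohorts.

### Below-LOQ handling, and a warning

The likelihood carries no censoring term (no M3-style integral). Below-LOQ
observations are flagged, and the `exclude_blq` switch controls whether
they enter the likelihood. For estimation experiments on synthetic cohorts
the package keeps them (`exclude_blq=False`): the generator records the
actual simulated value, and consistency runs at n=300 show that simply
dropping BLQ rows biases CL_pop by roughly −40% under this design (~7% of
samples censored, concentrated in the high-clearance subjects). This is a
real limitation for real assay data, where the sub-LOQ values are not
observable: there, exclusion is the only option this package offers, and
its clearance estimates should be expected to carry that bias. A censored
likelihood is the correct fix and is out of scope.

At the study's size (59 subjects, ~4 samples each) the per-subject data
nearly saturate the four random effects, and the exact marginal likelihood
can prefer degenerate modes (tiny typical CL with inflated ω²_CL) when BLQ
censoring distorts the data; with BLQ rows retained the parameter-recovery
experiment shows a −12% mean bias in CL_pop and an unbiased covariate slope
(mean 0.440 vs 0.437 generating value) over 20 replicate cohorts, with the
renal effect detected (forward ΔOFV > 3.84) in 85% of them.

### Validation operations

* **Diagnostics:** PRED (population prediction at η=0), IPRED (at η̂), and
  CWRES — residuals decorrelated by the first-order covariance
  G·Ω·G' + diag(σ²·IPRED²) with G = ∂f/∂η at the mode and first-order mean
  f(η̂) − G·η̂.
* **Bootstrap:** subjects resampled with replacement, each replicate refit
  from the supplied model; failed fits are counted and excluded from the
  per-parameter median and 2.5/97.5 percentiles.
* **pc-VPC:** observations and simulated replicates are rescaled by
  (bin-median PRED / subject PRED); bins sit at the design's scheduled
  times, merging bins with fewer than two observations. The result holds
  the observed 2.5/50/97.5 percentiles, the simulation-based 95% CI of each
  percentile, and the pooled simulated 95% band; under the true model
  ~95% of observations fall inside the band (the calibration test).

## Dosing simulation and PK/PD evaluation

Regimens are declared as dosing-table rules (day-1..3 rules plus a
maintenance rule from 72 h, mg/kg doses at an exact body weight — 975 mg
for 15 mg/kg at 65 kg, with a switch for clinically rounded amounts) and
expanded to infusion events on a 264 h horizon. Monte Carlo replicates
draw individual parameters at a fixed GFR and 65 kg (the study simulates a
typical 65 kg patient; no weight distribution), **without** residual error
— exposure metrics describe the individual's profile, not the assay. Three
metrics per replicate: the pre-dose troughs at 72 h and 240 h, and the
daily AUC.

The AUC window is the 24 h following the final maintenance dose: [240, 264]
for q24h maintenance and [216, 240] for q48h/q72h. This convention was
selected by direct comparison with the published dosing-table medians — it
reproduces the q24h rows and the q48h/q72h rows to within ~0.1–3%, whereas
time-normalizing over the full final interval undershoots the long-interval
rows by 12–19%. Defaults: 1,000 replicates per regimen (median MC error
~2–3%), 1 h infusions (the study allows 30–60 min; the difference is
negligible for troughs and daily AUC at a ~100 h half-life).

PTA at a MIC is the fraction of replicates with AUC/MIC ≥ 610 (boundary
inclusive); the MIC grid is {0.25, 0.5, 1, 2, 4} mg/L. CFR weights the
PTAs by an MRSA MIC histogram. **The shipped histogram is a synthetic
stand-in** shaped like surveillance data (mode at 0.5 mg/L); real CFR
estimates require substituting a current surveillance snapshot, and all
CFR outputs echo the distribution used. Regimen classification applies the
trough bands 15–30 mg/L (non-complicated) / 20–40 mg/L (complicated MRSA
infection), the AUC/MIC ≥ 610 and PTA ≥ 90% efficacy marks, and labels CFR
≥ 90% optimal and 80–90% a moderate probability of success.

## Problem sizes used in the shipped experiments

Parameter recovery runs 20 cohorts of 59 subjects (the study's size);
bootstrap examples run tens of replicates rather than the customary 1,000,
and the VPC calibration uses 150-subject cohorts with 200 simulation
replicates — large enough for the stochastic tolerances they are tested
at, and chosen so the whole suite runs comfortably on a laptop. The
Monte Carlo dosing experiments use the study's own 1,000 replicates.

## Known limitations

* No censored (M3) likelihood — see the BLQ warning above.
* No inter-occasion variability, ω covariance blocks, or combined
  additive+proportional error.
* Distribution volumes (V1, Q, V2) are weakly identified by trough-only
  sampling; synthetic-cohort fits recover CL and the renal slope much
  better than the volumes, and real sparse TDM data will do no better.
* The synthetic cohort's covariates are mutually independent; screening
  results say nothing about collinear covariate sets (e.g. Scr vs GFR).
* Standard errors / RSEs of fits are not computed; uncertainty comes from
  the bootstrap.
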