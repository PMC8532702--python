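# Methods

## Scope and model

`vancopk` implements a population pharmacokinetic analysis of intermittent
intravenous vancomycin in adult inpatients spanning the full range of renal
function, including augmented renal clearance (ARC, CLcr >= 130 mL/min), and
the Monte Carlo dose-optimization that turns the fitted model into
renal-function-stratified dosing recommendations.

Disposition is a two-compartment model with zero-order infusion input:
central volume `Vc`, peripheral volume `Vp`, inter-compartmental clearance
`Q`, and first-order elimination clearance `CL` from the central compartment.
The covariate model is

- `CL = CLmax * CLcr^s / (CG50^s + CLcr^s) * exp(eta1)` — a saturable (Hill)
  dependence on Cockcroft-Gault creatinine clearance.  `CLmax` (L/h) is the
  theoretical maximum clearance, `CG50` (mL/min) the creatinine clearance at
  which drug clearance is half-maximal, `s` a dimensionless steepness.
  The saturation means dose requirements stop rising at high CLcr.
- `Vc = Vc_nonICU` or `Vc_ICU` (times `exp(eta2)`) — an intensive-care shift
  of the central volume, reflecting fluid loading and capillary leak in the
  critically ill.
- `Q` and `Vp` carry no covariates or random effects.

Random effects `eta1`, `eta2` are normal with variances `omega2_cl`,
`omega2_vc` (lognormal parameter distributions).  Residual error is
proportional: `y = f * (1 + eps)`, `eps ~ N(0, sigma2)`.  The default
`PopulationModel` carries the published final estimates (CLmax 5.58 L/h,
CG50 93.8 mL/min, s 1.5, Vc 8.02/35.7 L, Q 2.66 L/h, Vp 36.8 L,
omega2 0.0771/0.223, sigma2 0.0466).  Note the source's parameter table
labels the residual term "additive" while its error equation is
proportional; the value 0.0466 is treated here as the variance of the
proportional model, consistent with that equation.

Serum creatinine is accepted in mg/dL or umol/L with a mandatory unit tag
(converted at 88.4 umol/L per mg/dL); when a subject has several creatinine
records, the per-subject mean CLcr over the admission is used.

## Closed-form kinetics

Concentrations are evaluated analytically.  With micro-constants
`k10 = CL/Vc`, `k12 = Q/Vc`, `k21 = Q/Vp`, the hybrid rate constants
`alpha, beta` are the roots of `x^2 - (k10+k12+k21) x + k10 k21 = 0`, and the
unit-bolus response is `(A e^{-alpha t} + B e^{-beta t})/Vc` with
`A = (alpha-k21)/(alpha-beta)`, `B = (k21-beta)/(alpha-beta)`.  Zero-order
infusions are the convolution of that response; dosing histories are
superposed (kinetics are linear).  When `|alpha-beta| < 1e-9 alpha` the
repeated-root limit form (`t e^{-lambda t}` terms) is substituted; with
`Q = 0` the `beta` term vanishes and the model collapses exactly to the
one-compartment infusion solution.

Steady-state exposure uses closed forms, not long simulation: the 24-h AUC
is daily dose / CL (exact for linear kinetics), and the trough applies the
geometric accumulation factor `1/(1-e^{-lambda tau})` to each exponential
term at the end of the interval.  Long-run superposition and numerical ODE
integration (`scipy.integrate.solve_ivp`, LSODA, rtol 1e-10) are kept as
test oracles only.

Default infusion durations are 1 h per dose, 2 h for doses >= 1500 mg
(common vancomycin practice; the source does not state durations); both are
configurable per dose event.

## Estimation (FOCE with interaction)

The marginal likelihood is approximated by the first-order conditional
method with interaction. Per subject:

1. the conditional mode `eta_hat` of the joint density of data and random
   effects is found by a damped Newton search (Gauss-Newton Hessian,
   backtracking line search), vectorized across all subjects; restarts at
   `eta = 0` every outer iteration for reproducibility;
2. the -2 log marginal likelihood contribution is the Laplace expression at
   `eta_hat` with the first-order Hessian including the interaction term of
   the proportional residual variance (`V = sigma2 f^2` depends on `eta`):
   `H = G'(V^{-1} + 2/f^2)G + Omega^{-1}`, where `G = df/deta`;
3. the objective (OFV) is the sum over subjects, including the `2 pi`
   constants.

`G` is obtained by finite differences of the prediction function (forward
during the Newton iterations, central at the mode).  The outer problem
optimizes log-transformed positive parameters (identity scale for sign-free
covariate coefficients) with L-BFGS-B; starting values come from a
naive-pooled least-squares pre-fit (`omega2 = 0.1`, `sigma2 = 0.05` as
variance starts).  Relative standard errors come from the central
finite-difference Hessian of the OFV at the optimum (covariance
`2 H^{-1}`), delta-method-transformed to the natural scale.  Against an
adaptive two-dimensional Gauss-Hermite quadrature oracle (15^2 nodes), the
OFV agrees to a few tenths of a unit on 10-subject cohorts.

Structural comparison fits one- and two-compartment base models and selects
by AIC = OFV + 2k.  The covariate search is forward addition (best drop in
OFV > 3.84 per step, chi-square p < 0.05 at 1 df) followed by backward
elimination from the full model (an effect is removed while removal raises
the OFV by <= 10.83, p < 0.001); every tested step is recorded in an audit
trail.  The thresholds are applied per candidate regardless of its parameter
count (the saturable form carries three parameters where the alternatives
carry one; in the published search all single steps were 1-df).  Clearance
versus CLcr can be fitted as saturable, linear, power or exponential;
continuous effects are centered at fixed references (CLcr 86.7 mL/min,
age 66 y, weight 63.4 kg — the study medians/means) so coefficients stay
comparable across cohorts.

## Synthetic cohorts

The hospital dataset is confidential, so all estimation-level evidence comes
from simulated cohorts that copy the study design: 209 subjects, 39.2% ICU,
60.3% male, age 66.0 +/- 16.4 y and weight 63.4 +/- 12.9 kg (truncated
normals), creatinine clearance drawn log-uniformly over the observed
18.4-390.7 mL/min support (populating the ARC tail; about a quarter of
subjects land at >= 130 mL/min), serum creatinine back-solved from the
target CLcr, and the published samples-per-patient table (1/2/3 samples with
probability 0.493/0.239/0.139; "4 or more" realized as uniform 4-6, giving
an expected total of ~425 concentrations against the study's 424).
Sampling times are drawn from the published post-infusion-window frequencies
(69.3% in the 5-12 h window) anchored at the last maintenance infusion.

The dosing policy is necessarily invented (the source reports only a median
daily dose of 1875 mg): an empiric 15 mg/kg q12h scaled by renal-function
band (0.4/0.6/0.8/1.0/1.3 below 30 / 30-60 / 60-90 / 90-130 / >= 130
mL/min), rounded to 250 mg and clipped to 250-2500 mg per dose, for a course
of 4-10 doses.  Observations are model predictions times `(1 + eps)`,
floored at a configurable assay quantification limit (default 0).

One seeded NumPy generator drives each cohort, drawing per subject in a
fixed order (demographics, CLcr, random effects, course length, sampling
windows and offsets, residuals), so cohorts regenerate bit-identically.

What the generator does not emulate: real creatinine trajectories within an
admission (one value per subject), clinician dose adjustments after drug
levels, correlated covariates (weight-CLcr, age-ICU), or diagnosis-driven
volume differences beyond the ICU flag (shock and multiple-organ-failure
flags are carried as metadata with roughly the study prevalences but have no
effect on the simulated kinetics).  Passing recovery tests therefore show
the estimator is consistent under the study design, not that the published
estimates are correct for the real population.  One visible consequence:
relative standard errors on synthetic cohorts are several-fold smaller than
the published ones, because the log-uniform CLcr spread is more informative
than the real cohort's concentrated distribution.

## Dose optimization

For each renal-function stratum (15-mL/min bands below 60 mL/min, 30-mL/min
bands above, up to 299), 10,000 virtual patients are drawn with CLcr uniform
within the band (the source does not state the within-stratum distribution;
the assumption is isolated in one place and swappable) and lognormal random
effects on CL and Vc.  Exposure is model-predicted — residual (assay) error
is excluded, because the targets concern true exposure — and the PTA is the
fraction inside the window (AUC24 400-650 mg.h/L, or trough 10-20 mg/L).
The grid is 250-2500 mg per dose in 250-mg steps at 8/12/24-h intervals.
Per stratum the regimen with the highest PTA wins; exact ties prefer fewer
daily administrations, then the lower total daily dose.  Because AUC24
equals daily dose / CL, regimens with equal daily dose are exactly
equivalent under the AUC target (and ICU status is irrelevant to it); the
trough target distinguishes them, and trough-target tables are reported
separately for ICU and non-ICU populations.  A report row for "CLcr >= 180"
merges the 180-299 bands with uniform sampling; dosing no longer rises
there because the clearance model has saturated.

`pta_semianalytic_auc` integrates the lognormal clearance tail probabilities
over the CLcr band by adaptive quadrature; it is the variance-free oracle
for the simulation and makes the uniform-CLcr assumption explicit.

## Numerical choices and problem sizes

- Inner Newton: active while the Newton decrement exceeds 1e-9; at most 40
  iterations, 12 step halvings; trial random effects clipped at |eta| = 40.
- Outer L-BFGS-B: ftol 1e-10, gradient step 1e-5 on the transformed scale,
  default budget 4000 objective evaluations.
- Predictions are floored at 1e-12 mg/L inside the likelihood so that
  pre-dose or washed-out records cannot produce infinite terms.
- Bootstrap: 1000 replicates by default in the pipeline; the test suite uses
  single-digit replicate counts, which exercise the resampling/refit
  machinery but not publication-grade intervals.  Replicate "success" is
  convergence with finite estimates; standard errors are not recomputed per
  replicate (the percentile intervals are the product of interest).
- pc-VPC: 8 equal-count bins on time after dose; prediction correction
  `y * median(PRED in bin)/PRED`; 1000 simulated datasets by default.
- Parameter-recovery evidence uses five seeded 209-subject cohorts; model
  selection and covariate-search tests use 40-80 subjects, chosen as the
  smallest cohorts at which the corresponding effects are decisively
  detectable.

## Known limitations

- No inter-occasion variability, no time-varying creatinine, no
  renal-replacement or acute-kidney-injury modeling (such patients were
  excluded from the source cohort), and no nonlinear elimination.
- FOCE-I is the only estimator (no SAEM or importance sampling).
- The published real-data AIC/OFV values and the bootstrap success rate are
  artifacts of the confidential dataset and cannot be reproduced here; the
  corresponding machinery is validated by self-consistency simulation
  (two-compartment truth selects two compartments; saturable-clearance truth
  yields the lowest OFV for the saturable form).
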