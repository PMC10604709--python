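# Methods

## Structural and statistical model

Disposition is a one-compartment model with first-order subcutaneous
absorption and linear elimination, in apparent (bioavailability-scaled)
parameters. For a dose `D` at time `t0`, the concentration contribution at
`t ≥ t0` is

    C(t) = D·ka / (V·(ka − ke)) · (e^{−ke·τ} − e^{−ka·τ}),   τ = t − t0,
    ke = (CL/F)/(V/F),

and dose histories superpose linearly. Adalimumab is in (or near) the
flip-flop regime — `ka = 0.00625 1/h` against `ke ≈ 0.004 1/h` at typical
parameters — so the difference of exponentials is evaluated as
`e^{−ka·τ}·expm1((ka−ke)·τ)`, which is cancellation-free arbitrarily close
to the `ka = ke` degeneracy; the analytic limit `D·ka·τ·e^{−ka·τ}/V` is used
only below `|ka−ke|/ka < 1e−12`. With this formulation the two branches agree
to better than 1e−9 relative at the switch, which a wider switch threshold
cannot achieve. Closed-form output is verified against adaptive ODE
integration of the depot/central system to 1e−6 relative in the test suite.

Covariates act on clearance only:

    CL/F = CL_pop · (1 + AAA·cov_AAA) · (ALB/m_ALB)^cov_ALB

with `m_ALB = 3.77 g/dL` (the population mean, a centering constant, never
estimated), `cov_AAA = 4.5` fixed (too few antibody-positive patients to
estimate it), and `cov_ALB` a free power exponent (negative: hypoalbuminaemic
patients clear faster). The covariate-search machinery additionally supports
generic power (continuous) and proportional-shift (categorical) effects on
CL/F for likelihood-ratio screening.

Interindividual variability is lognormal and independent across parameters:
`CL_i = CL_typ·e^{η_CL}`, `V_i = V_pop·e^{η_V}` with `η ~ N(0, diag(ω_CL²,
ω_V²))`; `ω` values are log-scale SDs. `ka` carries no IIV. The residual SD
is `a + b·f` ("combined1" convention; the quadrature alternative
`sqrt(a² + b²f²)` was considered and rejected so that the additive term acts
as a floor). The proportional model is the `a = 0` case; `a = b = 0` is
rejected as degenerate. The reported objective is OFV = −2·log-likelihood.

Two published parameter sets ship as constructors: the literature (reference)
model (`CL_pop 0.0175 L/h, V/F 13.5 L, ω_CL 0.65, ω_V 0.48, a 1.8 mg/L,
b 0.15`, no albumin effect) and the adopted (final) model (`CL_pop 0.0312,
V/F 7.76, cov_ALB −2.33, ω_CL 0.667, ω_V 0.477, b 0.547`, proportional
error).

## Estimation

Per subject, the empirical-Bayes estimate is the mode of the joint density of
data and random effects, found by damped Newton iteration with an analytic
gradient. The curvature used for Newton steps and for the marginal-likelihood
scaling is the expected information (Gauss–Newton) matrix

    H_i = Σ_j (1 + 2b²)·(∂f_j/∂η)(∂f_j/∂η)^T / sd_j² + Ω^{-1},

which is positive definite by construction (at least the η-prior precision).
This matters on sparse trough data: the observed Hessian can lose rank when
the residual-interaction term cancels the prior precision (flat individual
likelihood valleys), and a log-determinant built on it is violently
ill-conditioned, whereas the expected information varies smoothly. Subjects
that converge only linearly under Gauss–Newton steps switch to
observed-Hessian (finite-difference-of-gradient) steps after 15 iterations.
Convergence is per subject: gradient inf-norm below 1e−8, or Newton decrement
below 1e−10·(1+|nll|) where floating point cannot resolve the gradient
criterion (e.g. when an ω collapses toward 0). Non-converged subjects restart
from a deterministic grid of η values (±ω combinations); failures are flagged,
never silent. The solver is implemented twice — a fused numba kernel (default)
and a pure-numpy batched fallback — and the two agree to ~1e−13.

The marginal likelihood per subject is computed by adaptive Gauss–Hermite
quadrature: a 5×5 Hermite grid centred at the η mode and scaled by the
Cholesky factor of `H_i^{-1}`. One node reproduces the Laplace approximation
exactly (`OFV_i = 2·nll_i + log det H_i − 2 log 2π`); the default grid
integrates the skewness of the individual posteriors that Laplace misses.
This choice is consequential: under the adopted variability (`ω_CL = 0.667`,
`b = 0.547`) the pure Laplace/FOCE-style objective biased the recovered
`CL_pop` by ≈ +10% and attenuated `cov_ALB` by ≈ 6% on a 200-subject rich
design, while the 5-node grid brings both within ~1–4% and agrees with exact
2-d quadrature of a single-subject marginal to ~0.4%. The study's original
software fits by SAEM; this package's deterministic AGQ route is its own
design choice, with parameter recovery (not algorithm identity) as the
contract.

Population parameters are optimized by L-BFGS-B on centred, scaled
coordinates: log scale for positive parameters, natural scale for covariate
exponents; the per-parameter scale is the informative-prior width where one
exists (clamped to [1e−8, 0.3]) and 0.3/0.5 otherwise. Gradients are forward
finite differences of the objective (step 1e−4); convergence uses a relative
OFV tolerance of 1e−9. Inner solves always restart from η = 0 so the
objective is a deterministic, history-free function of the parameters (warm
starts were found to leak the evaluation path into the value when an η
posterior is multimodal). Uncertainties come from a central-difference
Hessian of the objective at the optimum; covariance = 2·H⁻¹ on the −2LL
scale, delta-method back to natural scale (RSE% of a log-scale parameter is
100·SE_log). A parameter with a flat Hessian direction reports an honest,
extremely wide interval rather than overflowing.

MAP estimation adds, per informative prior with mean `m` and relative
standard error `r`, the penalty `((log θ − log m)/r)²` for positive
parameters (lognormal kernel, RSE ≈ CV) and `((θ − m)/(|m|·r))²` for
sign-free ones (the albumin exponent cannot be lognormal). Normalizing
constants are deliberately dropped: the penalty is then minimized exactly at
the prior mean and each parameter's contribution vanishes in the
noninformative (large-r) limit, so a vague prior reproduces the plain
maximum-likelihood fit to the last bit.

Covariate selection is stepwise: forward addition accepts the candidate with
the smallest likelihood-ratio p-value below 0.01 (χ², 1 df; ties broken by
declaration order), backward elimination removes effects whose deletion gives
p > 0.01. Both thresholds are 0.01, matching the single threshold the study
states for the whole procedure.

The bootstrap resamples individuals with replacement to the original cohort
size (ids remapped to stay unique), refits each replicate from the full-data
estimates (replicates skip the Hessian step and use a slightly relaxed OFV
tolerance of 1e−7), and summarizes free parameters by mean, %RSE and
percentile 95% CIs. Non-converged replicates are excluded and counted. All
resampling is bit-reproducible from the seed.

## Evaluation

Leave-last-out: each subject's chronologically last trough is flagged and
excluded from the EBE solve; the model then predicts it. Bias is
MPE = mean(ŷ − y), imprecision RMSPE = sqrt(mean((ŷ − y)²)), both mg/L, with
subject-level bootstrap CIs; two models evaluated on the same subjects get
paired-difference CIs (a CI excluding 0 flags a significant difference).

The simulation-based checks (pcVPC, NPC, NPDE) simulate replicate cohorts at
the observed design points from the same observation model as the generator,
including the assay reporting floor (below). pcVPC bins observations by
quantiles of time-after-previous-dose (4 bins by default; the multiplicative
correction `y·median(PRED_bin)/PRED_i` suits the proportional error model)
and reports observed 5/50/95th percentiles per bin with simulated 95% bands.
NPC counts observations inside central prediction intervals (50/80/90/95% by
default) against the nominal level, with replicate-derived CIs and outlier
flags. NPDE decorrelates each subject's observed and simulated vectors with
the simulated mean and covariance (Cholesky; ridge-regularized with a warning
if singular), rank-transforms with midranks for ties via
`u = (#{sim < obs} + 0.5·#{sim = obs} + 0.5)/(n_sim + 1)`, and maps to normal
quantiles; the summary reports mean and variance with t- and χ²-test
p-values. An `include_induction` flag excludes the first two dosing intervals
from pcVPC/NPC if desired.

Clinical impact classifies each observed/forecast trough pair against the
8–12 mg/L window (boundaries belong to "within"). Per range: true positives
(both in the range), false positives (forecast in, observation out), observed
counts; subject-level bootstrap gives per-cell means and 95% CIs, reported
separately from the raw integer counts, plus paired-difference CIs when two
models are compared.

## Synthetic cohorts

The generator emulates the monitored IBD cohort: 54 subjects; 160/80 mg
induction at weeks 0/2 with 2/54 on an 80/40 variant; 40 mg every 336 h
maintenance (18 doses); 2–4 troughs per subject drawn as distinct maintenance
pre-dose times jittered U(0, 24 h) before the dose, with ~25% of subjects
contributing one induction trough (targeting ≈148 samples with ≈13% in the
induction phase); albumin truncated-normal (mean 3.77, SD 0.55, bounds
1.97–4.96 g/dL — chosen to match the reported median and range); AAA ~
Bernoulli(0.167). True per-subject η, CL, V and covariates are returned as a
sidecar table, never embedded in the dataset.

Observations are `y = f + (a + b·f)·ε` with a single standard-normal ε
(consistent with the likelihood's SD convention), clamped from below at the
assay's lower limit of quantification (0.1 mg/L, `reporting_floor`). Clamping
at the LOQ rather than 0 reflects how the assay reports (its range is
0.1–16 mg/L; nothing below 0.1 is ever reported) and keeps the
proportional-error likelihood bounded — an exact-zero observation makes the
Gaussian density diverge as the prediction approaches zero. The clamp
censors ≈3% of draws (P(ε < −1/b) with b = 0.547, independent of the design),
which is the price of modelling reported values without a censoring
likelihood (deliberately out of scope): it biases the fitted proportional
error low by ≈5%, slightly more than its own RSE on rich designs. `apply_loq`
offers keep/drop/floor policies for sub-LOQ handling; the main analysis keeps
values as reported.

A `rich_design` variant replaces sparse troughs with a fixed 8-point grid
(24–1007 h, including absorption-phase samples so V/F is identifiable with
`ka` fixed) and, in the recovery experiments, samples albumin uniformly over
1.97–4.96 g/dL to maximize covariate information — with the clinic's
truncated-normal albumin the exponent's standard error at 200 subjects
(~0.34) would be comparable to the recovery tolerance itself. This design
exists for identifiability experiments, not to mimic the clinic.

What passing the synthetic tests does and does not show: the generator draws
from exactly the fitted model family (no model misspecification, no
time-varying covariates, no dropout, no dose adaptation, no assay batch
effects), so recovery and calibration results demonstrate the correctness of
the estimation and diagnostic machinery, not the adequacy of the
one-compartment covariate model for any real population.

## Known limitations and honest failures

- Leave-last-out forecasts at the sparse study design carry a negative bias
  of ≈ −0.6 mg/L on self-simulated cohorts: the EBE-shrunk clearance
  under-disperses and the concentration is convex in η, so forecasts sit
  slightly below outcomes on average. This is the realistic magnitude — the
  study's own real-data bias for its final model is −0.849 mg/L — and it is
  a property of posterior-mode forecasting with 1–3 prior troughs, not an
  implementation artifact.
- The fitted proportional-error coefficient on generator data is ≈5% low
  (reporting-floor censoring, above); its Wald CI therefore tends to miss
  the generating value even though the estimate is well within practical
  tolerance.
- `ω_V` is weakly identified from troughs alone and may collapse toward 0 on
  sparse cohorts, with a correspondingly enormous RSE; the informative-prior
  (MAP) route exists precisely for this.
- Test-suite simulation scales (cohort counts, bootstrap replicate counts in
  the meta-experiments, power-study sizes of 100–150 subjects) were fixed a
  priori as the package's own reduced-scale study designs.
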