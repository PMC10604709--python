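# adapk — population pharmacokinetics of adalimumab in IBD

Adalimumab is an anti-TNF monoclonal antibody dosed subcutaneously in
inflammatory bowel disease (IBD). Its clearance varies several-fold between
patients — hypoalbuminaemic (more inflamed) patients and patients who develop
anti-adalimumab antibodies (AAA) clear the drug much faster — so clinics
increasingly individualize dosing from sparse trough serum concentrations
(TSC) with a population pharmacokinetic (PopPK) model and empirical-Bayes
forecasting (model-informed precision dosing, MIPD).

`adapk` implements that workflow end to end for pharmacometricians and
clinical-pharmacology researchers:

- **Model.** One-compartment kinetics with first-order absorption
  (`ka = 0.00625 1/h`, fixed: trough-only data carry no absorption
  information) and linear elimination, parameterized as apparent clearance
  and volume (CL/F, V/F). The covariate model on clearance is

  `CL/F = CL_pop · (1 + AAA · cov_AAA) · (ALB / 3.77)^cov_ALB`

  with serum albumin (g/dL) centred at the population mean and `cov_AAA =
  4.5` fixed. Interindividual variability is lognormal on CL/F and V/F
  (`ω_CL`, `ω_V` are log-scale SDs); the residual SD is `a + b·f`
  (proportional model: `a = 0`).
- **Estimation.** Deterministic nonlinear mixed-effects fitting: per-subject
  empirical-Bayes (posterior-mode) solves with an analytic gradient, and a
  marginal likelihood by mode-centred adaptive Gauss–Hermite quadrature
  (Laplace as the 1-node special case), optionally penalized by informative
  priors for maximum-a-posteriori estimation. RSEs and Wald intervals come
  from the inverse Hessian of the objective.
- **Evaluation.** Leave-last-out bias (MPE) and imprecision (RMSPE),
  prediction-corrected VPC, numerical predictive check, NPDE, and an
  individual (subject-resampling) bootstrap, plus a clinical-impact table of
  true/false positives against the 8–12 mg/L therapeutic trough window.
- **Synthetic cohorts.** A generator emulating the monitored IBD study
  design (54 patients, 160/80 mg induction, 40 mg q2w maintenance, 2–4
  jittered pre-dose troughs each, truncated-normal albumin, ~17% AAA), so the
  whole pipeline is testable without patient data.

## Worked example

```python
from adapk import PopPKModel, final_parameters
from adapk.simulate import DesignSpec, generate_cohort

cohort, truth = generate_cohort(DesignSpec(seed=42), final_parameters())
model = PopPKModel(cohort)          # defaults to the adopted covariate model
res = model.fit(seed=1)
print(res.summary())
```

```
Population PK fit (one-compartment, first-order absorption; Laplace)
  subjects: 54   observations: 153
  OFV (-2LL): 591.485   converged: True

           estimate       se  rse_pct  ci95_low  ci95_high
parameter
cl_pop      0.03083 0.003193    10.36   0.02516    0.03777
v_pop         6.743    1.741    25.83     4.064      11.19
cov_alb      -3.196   0.6388    19.99    -4.448     -1.944
omega_cl     0.6037  0.06834    11.32    0.4836     0.7536
omega_v      0.2548   0.2306    90.52   0.04321      1.502
err_prop     0.4919  0.03818    7.762    0.4224     0.5727

  fixed: cov_aaa=4.5, ka_pop=0.00625
```

The fit recovers the generating clearance (0.0312 L/h) within its 10% RSE and
finds the negative albumin exponent; `omega_v` is poorly identified from
troughs alone (RSE 91%) — exactly the situation in which the study turned to
informative priors (`PriorSpec`, `adapk.reference_priors()`).

```python
perf = res.performance(seed=1)       # leave-last-out forecasting
print(perf.mpe, perf.rmspe)
table = res.impact(n_reps=500, seed=1)
```

```
leave-last-out bias (MPE): -0.06 mg/L  (95% CI -0.72 : 0.59)
imprecision (RMSPE):       2.33 mg/L  (95% CI 1.64 : 3.09)
```

so the forecast of each patient's next trough is essentially unbiased with
~2.3 mg/L spread, and `table` counts, per therapeutic range (below / within /
above 8–12 mg/L), how often forecast and observation agree (true positives)
or the forecast lands in a range the observation does not (false positives),
with bootstrap 95% CIs.

A thin CLI mirrors the library:

```bash
adapk simulate --n 54 --seed 7 --out cohort.csv --truth truth.csv
adapk fit --data cohort.csv --seed 1 --out fit.json
adapk evaluate --data cohort.csv --model fit.json --check loo --seed 1
adapk impact --data cohort.csv --model fit.json --reps 500 --seed 1
```

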