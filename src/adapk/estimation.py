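"""Nonlinear mixed-effects estimation for the adalimumab model.

The marginal likelihood is approximated by the Laplace method at the
empirical-Bayes mode of each subject's random effects (a FOCE-like,
deterministic approximation).  Population parameters are optimized on the log
scale (covariate exponents unconstrained), optionally penalized by informative
priors for maximum-a-posteriori estimation, with relative standard errors from
the inverse Hessian of the objective at the optimum.

Also here: likelihood-ratio covariate selection (forward addition / backward
elimination at p < 0.01) and the nonparametric bootstrap that resamples
individuals with replacement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._core import CohortArrays, laplace_terms, solve_ebes
from .data import Cohort, Subject
from .population import (
    LOG_SCALE_PARAMS,
    PARAMETER_NAMES,
    PopulationParameters,
    PriorSpec,
    RandomEffects,
    prior_penalty,
)

__all__ = [
    "CovariateSpec",
    "CovariateEffect",
    "FitResult",
    "BootstrapResult",
    "SelectionResult",
    "estimate_ebe",
    "laplace_ofv",
    "fit_population",
    "covariate_lrt",
    "stepwise_covariate_search",
    "bootstrap_fit",
]

class _SkipUncertainty(Exception):
    """Internal: replicate fits skip the Hessian-based uncertainty step."""


# outer optimizer knobs (scaled coordinates)
_OUTER_FTOL = 1e-9
_OUTER_GTOL = 1e-5
_GRAD_STEP = 1e-4
_HESS_STEP = 1e-3
_DEFAULT_SCALE_LOG = 0.3
_DEFAULT_SCALE_LIN = 0.5


@dataclass(frozen=True)
class CovariateSpec:
    """A candidate covariate effect on apparent clearance.

    ``form`` is ``"power"`` for continuous covariates (centred at ``center``,
    null exponent 0) or ``"proportional"`` for categorical ones (null shift 0).
    The albumin power effect maps onto the built-in ``cov_alb`` parameter.
    """

    covariate: str
    form: str = "power"
    center: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("power", "proportional"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    @property
    def is_builtin_albumin(self) -> bool:
        return self.covariate in ("alb", "albumin") and self.form == "power"

    @property
    def param_name(self) -> str:
        return "cov_alb" if self.is_builtin_albumin else f"beta_{self.covariate}"


@dataclass(frozen=True)
class CovariateEffect:
    """A fitted extra covariate effect (value attached to a CovariateSpec)."""

    covariate: str
    form: str
    value: float
    center: float | None = None

    @property
    def param_name(self) -> str:
        return f"beta_{self.covariate}"


@dataclass(frozen=True)
class FitResult:
    """Population-fit output: estimates, uncertainties and per-subject EBEs."""

    estimates: PopulationParameters
    extra_effects: tuple[CovariateEffect, ...]
    se: Mapping[str, float]  # natural-scale standard errors (free params)
    rse: Mapping[str, float]  # % relative standard errors (free params)
    ci: Mapping[str, tuple[float, float]]  # 95% Wald intervals, natural scale
    ofv: float
    converged: bool
    message: str
    n_iter: int
    ebes: Mapping[str, RandomEffects]
    n_subjects: int
    n_obs: int
    seed: int
    free_names: tuple[str, ...]

    def param_value(self, name: str) -> float:
        for eff in self.extra_effects:
            if eff.param_name == name:
                return eff.value
        return self.estimates.get(name)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.free_names:
            lo, hi = self.ci.get(name, (math.nan, math.nan))
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.param_value(name),
                    "se": self.se.get(name, math.nan),
                    "rse_pct": self.rse.get(name, math.nan),
                    "ci95_low": lo,
                    "ci95_high": hi,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class BootstrapResult:
    """Per-parameter bootstrap distribution over individual-resampled refits."""

    replicates: tuple[FitResult, ...]
    summary: pd.DataFrame  # index: parameter; mean, sd, rse_pct, ci2.5, ci97.5
    n_requested: int
    n_failed: int
    seed: int

    @property
    def exclusion_rate(self) -> float:
        return self.n_failed / self.n_requested if self.n_requested else 0.0

    def ci(self, name: str) -> tuple[float, float]:
        row = self.summary.loc[name]
        return float(row["ci2.5"]), float(row["ci97.5"])


def _free_parameter_names(
    init: PopulationParameters, fixed: frozenset, extra_effects: Sequence[CovariateEffect]
) -> list[str]:
    names = [n for n in PARAMETER_NAMES if n not in fixed and n != "m_alb"]
    # m_alb is a centering constant, never estimated
    names += [eff.param_name for eff in extra_effects]
    return names


def _build_scales(
    names: Sequence[str], priors: PriorSpec
) -> np.ndarray:
    scales = []
    informative = priors.informative()
    for n in names:
        default = _DEFAULT_SCALE_LOG if n in LOG_SCALE_PARAMS else _DEFAULT_SCALE_LIN
        if n in informative:
            e = informative[n]
            s = e.prior_rse if n in LOG_SCALE_PARAMS else abs(e.prior_mean) * e.prior_rse
            # precondition by the prior width, clamped so a vague prior
            # behaves exactly like no prior
            scales.append(min(max(s, 1e-8), default))
        else:
            scales.append(default)
    return np.asarray(scales)


class _Objective:
    """Laplace OFV + prior penalty as a function of scaled free parameters."""

    def __init__(self, arr, init, fixed, priors, extra_effects):
        self.arr = arr
        self.init = init
        self.fixed = fixed
        self.priors = priors
        self.base_effects = tuple(extra_effects)
        self.names = _free_parameter_names(init, fixed, self.base_effects)
        self.scales = _build_scales(self.names, priors)
        self.n_evals = 0

        raw0 = []
        for n in self.names:
            if n.startswith("beta_"):
                val = next(e.value for e in self.base_effects if e.param_name == n)
                raw0.append(val)
            else:
                val = init.get(n)
                if n in LOG_SCALE_PARAMS:
                    if val <= 0:
                        raise ValueError(f"initial {n} must be > 0 to estimate it (got {val})")
                    val = math.log(val)
                raw0.append(val)
        # optimize centered, scaled offsets: x = (raw - raw0) / scale
        self.raw0 = np.asarray(raw0)
        self.x0 = np.zeros(len(self.names))

    def decode(self, x: np.ndarray):
        raw = np.asarray(x) * self.scales + self.raw0
        updates = {}
        effect_vals = {}
        for n, v in zip(self.names, raw):
            if n.startswith("beta_"):
                effect_vals[n] = v
            elif n in LOG_SCALE_PARAMS:
                # clip: keeps exp finite when the line search overshoots
                updates[n] = math.exp(min(max(v, -200.0), 200.0))
            else:
                updates[n] = v
        pop = self.init.with_values(**updates) if updates else self.init
        effects = tuple(
            replace(e, value=effect_vals.get(e.param_name, e.value))
            for e in self.base_effects
        )
        return pop, effects

    def __call__(self, x: np.ndarray) -> float:
        pop, effects = self.decode(x)
        try:
            # inner solves always start from eta = 0: the objective must be a
            # deterministic, history-free function of x (warm starts leak the
            # evaluation path into the value when an eta posterior is multimodal)
            ofv_i, eta, conv = laplace_terms(self.arr, pop, extra_effects=effects)
        except (FloatingPointError, ValueError):
            return 1e12
        self.n_evals += 1
        ofv = float(ofv_i.sum())
        if not np.isfinite(ofv):
            return 1e12
        return ofv + prior_penalty(pop, self.priors)

    def value_and_grad(self, x: np.ndarray):
        # forward differences: one extra evaluation per free parameter; the
        # O(h) truncation bias is well below the estimation uncertainty
        f0 = self(x)
        g = np.empty_like(x)
        for k in range(len(x)):
            h = _GRAD_STEP * max(1.0, abs(x[k]))
            xp = x.copy()
            xp[k] += h
            g[k] = (self(xp) - f0) / h
        return f0, g

    def hessian(self, x: np.ndarray) -> np.ndarray:
        k = len(x)
        H = np.empty((k, k))
        h = _HESS_STEP * np.maximum(1.0, np.abs(x))
        f0 = self(x)
        fp = np.empty(k)
        fm = np.empty(k)
        for i in range(k):
            xp = x.copy()
            xp[i] += h[i]
            xm = x.copy()
            xm[i] -= h[i]
            fp[i] = self(xp)
            fm[i] = self(xm)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                xpp = x.copy()
                xpp[[i, j]] += h[[i, j]]
                xmm = x.copy()
                xmm[[i, j]] -= h[[i, j]]
                H[i, j] = H[j, i] = (
                    self(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + self(xmm)
                ) / (2 * h[i] * h[j])
        return H


def estimate_ebe(
    subject: Subject,
    pop: PopulationParameters,
    *,
    use_held_out: bool = True,
    extra_effects: Sequence[CovariateEffect] = (),
) -> RandomEffects:
    """Empirical-Bayes estimate (posterior mode) of one subject's random effects.

    With ``use_held_out=False`` observations flagged ``held_out`` contribute
    nothing, so a subject whose only observations are held out shrinks fully
    to the population (eta = 0).  Non-convergence after the deterministic
    multi-start is flagged on the returned object and warned about, never
    silently dropped.
    """
    arr = CohortArrays(Cohort(subjects=(subject,), meta={}), use_held_out=use_held_out)
    eta, f, g, H, conv = solve_ebes(arr, pop, extra_effects=tuple(extra_effects))
    if not bool(conv[0]):
        warnings.warn(
            f"EBE solve did not reach gradient tolerance for subject {subject.id} "
            f"(grad inf-norm {np.max(np.abs(g[0])):.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return RandomEffects(eta_cl=float(eta[0, 0]), eta_v=float(eta[0, 1]), converged=bool(conv[0]))


def laplace_ofv(
    cohort: Cohort,
    pop: PopulationParameters,
    *,
    use_held_out: bool = True,
    extra_effects: Sequence[CovariateEffect] = (),
) -> float:
    """Laplace-approximate -2 log marginal likelihood of the cohort.

    Deterministic given data and parameters: inner solves always start from
    eta = 0 with a fixed restart grid.
    """
    arr = CohortArrays(cohort, use_held_out=use_held_out)
    ofv_i, _, _ = laplace_terms(arr, pop, extra_effects=tuple(extra_effects))
    return float(ofv_i.sum())


def fit_population(
    cohort: Cohort,
    init: PopulationParameters,
    priors: PriorSpec | None = None,
    *,
    fixed: Iterable[str] | None = None,
    extra_effects: Sequence[CovariateEffect] = (),
    use_held_out: bool = True,
    seed: int = 0,
    maxiter: int = 300,
    compute_uncertainty: bool = True,
    ftol: float = _OUTER_FTOL,
) -> FitResult:
    """Fit population parameters by penalized Laplace maximum likelihood.

    Positive parameters are optimized on the log scale; covariate exponents on
    the natural scale.  ``priors`` adds the MAP penalty (noninformative priors
    reproduce the plain maximum-likelihood fit).  Parameters named in
    ``fixed`` (default: ``init.fixed``) are held at their initial values; with
    everything fixed this is a pure evaluation and no uncertainties are
    produced.  Optimizer failure yields a non-converged result carrying the
    best values found, not an exception.
    """
    priors = priors or PriorSpec.noninformative()
    fixed_set = frozenset(fixed) if fixed is not None else frozenset(init.fixed)
    init = init.with_values(fixed=fixed_set)
    arr = CohortArrays(cohort, use_held_out=use_held_out)
    obj = _Objective(arr, init, fixed_set, priors, extra_effects)

    if not obj.names:  # fully fixed: pure evaluation
        ofv = laplace_ofv(cohort, init, use_held_out=use_held_out, extra_effects=extra_effects)
        eta, *_ = solve_ebes(arr, init, extra_effects=tuple(extra_effects))
        ebes = {
            sid: RandomEffects(float(e[0]), float(e[1])) for sid, e in zip(arr.ids, eta)
        }
        return FitResult(
            estimates=init,
            extra_effects=tuple(extra_effects),
            se={},
            rse={},
            ci={},
            ofv=ofv,
            converged=True,
            message="all parameters fixed: evaluation only",
            n_iter=0,
            ebes=ebes,
            n_subjects=arr.n,
            n_obs=arr.n_lik_obs,
            seed=seed,
            free_names=(),
        )

    res = optimize.minimize(
        obj.value_and_grad,
        obj.x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": ftol, "gtol": _OUTER_GTOL},
    )
    x_hat = res.x
    pop_hat, effects_hat = obj.decode(x_hat)
    ofv = float(obj(x_hat))

    # uncertainties: inverse Hessian of the objective, delta method to natural scale
    se: dict[str, float] = {}
    rse: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    try:
        if not compute_uncertainty:
            raise _SkipUncertainty
        H = obj.hessian(x_hat)
        cov_x = 2.0 * np.linalg.pinv(0.5 * (H + H.T))
        var_x = np.diag(cov_x)
        if np.any(var_x < 0):
            warnings.warn("objective Hessian not positive definite at optimum", RuntimeWarning)
        for k, name in enumerate(obj.names):
            sd_raw = math.sqrt(max(var_x[k], 0.0)) * obj.scales[k]
            theta = (
                effects_hat[[e.param_name for e in effects_hat].index(name)].value
                if name.startswith("beta_")
                else pop_hat.get(name)
            )
            if name in LOG_SCALE_PARAMS:
                se[name] = abs(theta) * sd_raw
                rse[name] = 100.0 * sd_raw
                # clip the exponent: an unidentified parameter (flat Hessian)
                # gets an honest (0, inf)-like interval instead of an overflow
                half = min(1.96 * sd_raw, 700.0)
                ci[name] = (theta * math.exp(-half), theta * math.exp(half))
            else:
                se[name] = sd_raw
                rse[name] = 100.0 * sd_raw / abs(theta) if theta != 0 else math.inf
                ci[name] = (theta - 1.96 * sd_raw, theta + 1.96 * sd_raw)
    except _SkipUncertainty:
        pass
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate Hessian
        warnings.warn("could not invert objective Hessian; no RSEs", RuntimeWarning)

    eta, _, g, _, conv = solve_ebes(arr, pop_hat, extra_effects=effects_hat)
    ebes = {sid: RandomEffects(float(e[0]), float(e[1]), converged=bool(c))
            for sid, e, c in zip(arr.ids, eta, conv)}
    return FitResult(
        estimates=pop_hat,
        extra_effects=effects_hat,
        se=se,
        rse=rse,
        ci=ci,
        ofv=ofv,
        converged=bool(res.success),
        message=str(res.message),
        n_iter=int(res.nit),
        ebes=ebes,
        n_subjects=arr.n,
        n_obs=arr.n_lik_obs,
        seed=seed,
        free_names=tuple(obj.names),
    )


def _extended_fit(
    cohort: Cohort,
    base_fit: FitResult,
    candidate: CovariateSpec,
    priors: PriorSpec | None,
    **fit_kw,
) -> FitResult:
    init = base_fit.estimates
    effects = list(base_fit.extra_effects)
    if candidate.is_builtin_albumin:
        if "cov_alb" not in init.fixed:
            raise ValueError(
                "candidate does not nest the base model: cov_alb is already free"
            )
        fixed = frozenset(init.fixed) - {"cov_alb"}
        init = init.with_values(fixed=fixed)
    else:
        if any(e.covariate == candidate.covariate for e in effects):
            raise ValueError(
                f"candidate {candidate.covariate!r} already present in the base model"
            )
        fixed = frozenset(init.fixed)
        center = candidate.center
        if center is None and candidate.form == "power":
            center = float(
                np.mean([s.covariates[candidate.covariate] for s in cohort])
            )
        effects.append(
            CovariateEffect(candidate.covariate, candidate.form, 0.0, center)
        )
    fixed = fit_kw.pop("fixed", fixed)
    return fit_population(
        cohort, init, priors, fixed=fixed, extra_effects=tuple(effects), **fit_kw
    )


def covariate_lrt(
    cohort: Cohort,
    base_fit: FitResult,
    candidate: CovariateSpec,
    *,
    priors: PriorSpec | None = None,
    threshold: float = 0.01,
    **fit_kw,
) -> tuple[float, float, bool]:
    """Likelihood-ratio test of one nested covariate extension.

    Returns ``(delta_ofv, p_value, accepted)`` with ``delta_ofv`` the OFV drop
    from adding the single extra parameter, ``p`` from chi-square with 1 df,
    and acceptance at ``p < threshold`` (the study used 0.01).
    """
    ext = _extended_fit(cohort, base_fit, candidate, priors, **fit_kw)
    delta = base_fit.ofv - ext.ofv
    p = float(stats.chi2.sf(max(delta, 0.0), df=1))
    return delta, p, p < threshold


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the stepwise covariate search."""

    fit: FitResult
    selected: tuple[CovariateSpec, ...]
    trace: tuple[dict, ...] = field(default_factory=tuple)


def stepwise_covariate_search(
    cohort: Cohort,
    base_fit: FitResult,
    candidates: Sequence[CovariateSpec],
    *,
    priors: PriorSpec | None = None,
    alpha: float = 0.01,
    **fit_kw,
) -> SelectionResult:
    """Forward-addition / backward-elimination covariate search on CL/F.

    Forward: repeatedly add the candidate with the smallest p-value below
    ``alpha`` (ties broken by declaration order).  Backward: repeatedly drop
    the included effect whose removal gives the largest p-value above
    ``alpha``.  Deterministic given the data.
    """
    current = base_fit
    remaining = list(candidates)
    selected: list[CovariateSpec] = []
    trace: list[dict] = []

    while remaining:
        # drop candidates the current model can no longer nest
        remaining = [
            s
            for s in remaining
            if (s.is_builtin_albumin and "cov_alb" in current.estimates.fixed)
            or (
                not s.is_builtin_albumin
                and not any(e.covariate == s.covariate for e in current.extra_effects)
            )
        ]
        if not remaining:
            break
        results = []
        for spec in remaining:
            fit = _extended_fit(cohort, current, spec, priors, **fit_kw)
            delta = current.ofv - fit.ofv
            p = float(stats.chi2.sf(max(delta, 0.0), df=1))
            results.append((p, spec, fit, delta))
            trace.append(
                {"step": "forward", "candidate": spec.covariate, "delta_ofv": delta, "p": p}
            )
        best_idx = min(range(len(results)), key=lambda k: results[k][0])
        p, spec, fit, delta = results[best_idx]
        if p >= alpha:
            break
        selected.append(spec)
        remaining = [s for s in remaining if s is not spec]
        current = fit

    removed = True
    while removed and selected:
        removed = False
        results = []
        for spec in selected:
            reduced = _reduced_fit(cohort, current, spec, priors, **fit_kw)
            delta = reduced.ofv - current.ofv
            p = float(stats.chi2.sf(max(delta, 0.0), df=1))
            results.append((p, spec, reduced, delta))
            trace.append(
                {"step": "backward", "candidate": spec.covariate, "delta_ofv": delta, "p": p}
            )
        worst_idx = max(range(len(results)), key=lambda k: results[k][0])
        p, spec, reduced, delta = results[worst_idx]
        if p > alpha:
            selected = [s for s in selected if s is not spec]
            current = reduced
            removed = True

    return SelectionResult(fit=current, selected=tuple(selected), trace=tuple(trace))


def _reduced_fit(cohort, full_fit, spec: CovariateSpec, priors, **fit_kw) -> FitResult:
    init = full_fit.estimates
    effects = list(full_fit.extra_effects)
    if spec.is_builtin_albumin:
        init = init.with_values(cov_alb=0.0, fixed=frozenset(init.fixed) | {"cov_alb"})
    else:
        effects = [e for e in effects if e.covariate != spec.covariate]
    return fit_population(
        cohort, init, priors, fixed=init.fixed, extra_effects=tuple(effects), **fit_kw
    )


def bootstrap_fit(
    cohort: Cohort,
    init: PopulationParameters,
    priors: PriorSpec | None = None,
    *,
    n_reps: int = 500,
    seed: int = 0,
    extra_effects: Sequence[CovariateEffect] = (),
    maxiter: int = 150,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample individuals, refit, summarize.

    Each replicate draws ``n_subjects`` subjects with replacement (ids
    remapped to stay unique), refits from ``init`` and contributes its free
    parameters to the per-parameter mean, %RSE and percentile 95% CI.
    Non-converged replicates are excluded and counted.  Bit-reproducible
    under a fixed ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = list(cohort)
    n = len(subjects)
    reps: list[FitResult] = []
    n_failed = 0
    for r in range(n_reps):
        idx = rng.integers(0, n, size=n)
        resampled = tuple(
            replace(subjects[i], id=f"{subjects[i].id}~{k}") for k, i in enumerate(idx)
        )
        boot = Cohort(subjects=resampled, meta={"bootstrap_rep": r})
        fit = fit_population(
            boot, init, priors, fixed=init.fixed, extra_effects=extra_effects,
            seed=seed, maxiter=maxiter, compute_uncertainty=False, ftol=1e-7,
        )
        if fit.converged:
            reps.append(fit)
        else:
            n_failed += 1
    if not reps:
        raise RuntimeError("all bootstrap replicates failed to converge")

    names = reps[0].free_names
    table = {}
    for name in names:
        vals = np.array([f.param_value(name) for f in reps])
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        table[name] = {
            "mean": mean,
            "sd": sd,
            "rse_pct": 100.0 * sd / abs(mean) if mean != 0 else math.inf,
            "ci2.5": float(np.percentile(vals, 2.5)),
            "ci97.5": float(np.percentile(vals, 97.5)),
        }
    summary = pd.DataFrame(table).T
    return BootstrapResult(
        replicates=tuple(reps),
        summary=summary,
        n_requested=n_reps,
        n_failed=n_failed,
        seed=seed,
    )
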