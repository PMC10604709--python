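"""Predictive-performance evaluation: leave-last-out bias/imprecision,
prediction-corrected VPC, numerical predictive check and NPDE.

The clinical question behind these diagnostics is whether a dosing model can
forecast the next trough concentration of a monitored patient.  The
leave-last-out scheme mimics that use: each patient's final trough is hidden,
the empirical-Bayes estimates are computed from the earlier troughs only, and
the hidden trough is predicted.  Bias is the mean prediction error
MPE = mean(y_pred - y_obs) and imprecision the root mean square prediction
error RMSPE = sqrt(mean((y_pred - y_obs)^2)), both in mg/L.

The simulation-based checks (pcVPC, NPC, NPDE) simulate replicate cohorts at
the observed design points from the same observation model as the synthetic
generator (combined/proportional noise, floored at zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._core import CohortArrays, predict, solve_ebes, typical_cl
from .data import Cohort
from .population import PopulationParameters
from .structural import profile

__all__ = [
    "PredictionPair",
    "PerformanceSummary",
    "leave_last_out_predict",
    "mpe",
    "rmspe",
    "bootstrap_performance",
    "pcvpc",
    "npc",
    "npde",
    "NpdeResult",
    "plot_pcvpc",
]


@dataclass(frozen=True)
class PredictionPair:
    """Held-out observed trough and its individual (EBE-based) prediction."""

    subject_id: str
    y_obs: float
    y_pred: float

    def __post_init__(self) -> None:
        if self.y_obs < 0 or self.y_pred < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class PerformanceSummary:
    """Bias (MPE) and imprecision (RMSPE) with bootstrap 95% intervals."""

    mpe: float
    rmspe: float
    n: int
    ci_mpe: tuple[float, float] | None = None
    ci_rmspe: tuple[float, float] | None = None


def _as_pop(model) -> tuple[PopulationParameters, tuple]:
    """Accept PopulationParameters or a FitResult-like object."""
    if hasattr(model, "estimates"):
        return model.estimates, tuple(getattr(model, "extra_effects", ()))
    return model, ()


def leave_last_out_predict(cohort: Cohort, model) -> list[PredictionPair]:
    """Predict each subject's held-out last trough from the earlier troughs.

    ``cohort`` must have been processed by :func:`adapk.data.hold_out_last`.
    Population parameters stay fixed; only the random effects are estimated,
    per subject, from the non-held-out observations.  Subjects whose EBE solve
    fails to converge are excluded with a warning.
    """
    pop, effects = _as_pop(model)
    arr = CohortArrays(cohort, use_held_out=False)
    if not arr.held_mask.any():
        raise ValueError("cohort has no held-out observations; call hold_out_last first")
    per_subject = arr.held_mask.sum(axis=1)
    if np.any(per_subject != 1):
        bad = [arr.ids[i] for i in np.where(per_subject != 1)[0]]
        raise ValueError(f"expected exactly one held-out observation per subject: {bad}")

    eta, f, g, H, conv = solve_ebes(arr, pop, extra_effects=effects)
    pred = predict(arr, pop, eta, extra_effects=effects)
    pairs = []
    n_dropped = 0
    for i in range(arr.n):
        if not conv[i]:
            n_dropped += 1
            continue
        j = int(np.argmax(arr.held_mask[i]))
        pairs.append(
            PredictionPair(
                subject_id=arr.ids[i],
                y_obs=float(arr.y[i, j]),
                y_pred=float(max(pred[i, j], 0.0)),
            )
        )
    if n_dropped:
        warnings.warn(
            f"{n_dropped} subject(s) excluded from leave-last-out (EBE non-convergence)",
            RuntimeWarning,
            stacklevel=2,
        )
    return pairs


def mpe(pairs: Sequence[PredictionPair]) -> float:
    """Mean prediction error (bias), mg/L: mean of (y_pred - y_obs)."""
    if not pairs:
        raise ValueError("mpe requires at least one prediction pair")
    return float(np.mean([p.y_pred - p.y_obs for p in pairs]))


def rmspe(pairs: Sequence[PredictionPair]) -> float:
    """Root mean square prediction error (imprecision), mg/L."""
    if not pairs:
        raise ValueError("rmspe requires at least one prediction pair")
    return float(np.sqrt(np.mean([(p.y_pred - p.y_obs) ** 2 for p in pairs])))


def bootstrap_performance(
    cohort: Cohort,
    models: Mapping[str, object],
    *,
    n_reps: int = 500,
    seed: int = 0,
) -> tuple[dict[str, PerformanceSummary], pd.DataFrame]:
    """Bootstrap bias/imprecision per model and their pairwise differences.

    Prediction pairs are computed once per model on the same subjects; the
    bootstrap then resamples subjects with replacement and recomputes
    MPE/RMSPE per replicate per model and the paired differences.  A
    difference whose percentile 95% CI excludes 0 is flagged significant.
    """
    names = list(models)
    all_pairs = {name: leave_last_out_predict(cohort, models[name]) for name in names}
    ids = [p.subject_id for p in all_pairs[names[0]]]
    for name in names[1:]:
        if [p.subject_id for p in all_pairs[name]] != ids:
            raise ValueError("models produced pairs for different subject sets")
    n = len(ids)
    if n < 2:
        raise ValueError("bootstrap_performance requires at least 2 subjects")

    err = {
        name: np.array([p.y_pred - p.y_obs for p in all_pairs[name]])
        for name in names
    }
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_reps, n))
    reps_mpe = {name: err[name][idx].mean(axis=1) for name in names}
    reps_rmspe = {name: np.sqrt((err[name][idx] ** 2).mean(axis=1)) for name in names}

    summaries = {}
    for name in names:
        summaries[name] = PerformanceSummary(
            mpe=float(err[name].mean()),
            rmspe=float(np.sqrt((err[name] ** 2).mean())),
            n=n,
            ci_mpe=tuple(np.percentile(reps_mpe[name], [2.5, 97.5])),
            ci_rmspe=tuple(np.percentile(reps_rmspe[name], [2.5, 97.5])),
        )

    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            na, nb = names[a], names[b]
            for metric, reps in (("mpe", reps_mpe), ("rmspe", reps_rmspe)):
                diff = reps[na] - reps[nb]
                lo, hi = np.percentile(diff, [2.5, 97.5])
                rows.append(
                    {
                        "model_a": na,
                        "model_b": nb,
                        "metric": metric,
                        "difference": float(diff.mean()),
                        "ci95_low": float(lo),
                        "ci95_high": float(hi),
                        "significant": bool(lo > 0 or hi < 0),
                    }
                )
    return summaries, pd.DataFrame(rows)


def _time_after_dose(arr: CohortArrays) -> np.ndarray:
    """Time since the most recent dose for every observation slot, (n, m)."""
    dose_t = np.where(arr.dose_a > 0, arr.dose_t, -np.inf)  # ignore padding
    prev = np.where(
        dose_t[:, None, :] <= arr.t[:, :, None], dose_t[:, None, :], -np.inf
    ).max(axis=2)
    return arr.t - prev


# assay lower limit of quantification: simulated observations are clamped
# here, mirroring how the measured concentrations are reported
ASSAY_FLOOR = 0.1


def _simulate_observations(
    arr: CohortArrays,
    pop: PopulationParameters,
    n_sim: int,
    rng: np.random.Generator,
    extra_effects=(),
) -> np.ndarray:
    """Replicate observation matrices (n_sim, n, m) from the model at the design."""
    n, m = arr.t.shape
    cl_typ = typical_cl(pop, arr, extra_effects)
    eta = rng.normal(0.0, 1.0, size=(n_sim, n, 2)) * np.array(
        [pop.omega_cl, pop.omega_v]
    )
    cl = cl_typ[None, :] * np.exp(eta[:, :, 0])
    v = pop.v_pop * np.exp(eta[:, :, 1])
    dose_t = np.broadcast_to(arr.dose_t, (n_sim,) + arr.dose_t.shape).reshape(
        n_sim * n, -1
    )
    dose_a = np.broadcast_to(arr.dose_a, (n_sim,) + arr.dose_a.shape).reshape(
        n_sim * n, -1
    )
    times = np.broadcast_to(arr.t, (n_sim,) + arr.t.shape).reshape(n_sim * n, -1)
    f = profile(cl.ravel(), v.ravel(), pop.ka_pop, dose_t, dose_a, times)
    f = f.reshape(n_sim, n, m)
    sd = pop.err_add + pop.err_prop * f
    y = f + sd * rng.normal(0.0, 1.0, size=f.shape)
    return np.maximum(y, ASSAY_FLOOR)


def pcvpc(
    cohort: Cohort,
    model,
    *,
    n_sim: int = 500,
    bins: int = 4,
    seed: int = 0,
    include_induction: bool = True,
) -> pd.DataFrame:
    """Prediction-corrected visual predictive check table.

    Observations are rescaled by the ratio of the bin-median population
    prediction to each point's own population prediction (multiplicative
    correction, appropriate for proportional error), binned by quantiles of
    time-after-previous-dose.  ``n_sim`` replicate cohorts simulated at the
    same design points receive the identical correction; the table reports
    the observed 5/50/95th percentiles per bin with the simulated 95%
    confidence band for each percentile.
    """
    pop, effects = _as_pop(model)
    arr = CohortArrays(cohort)
    rng = np.random.default_rng(seed)

    pred_pop = predict(arr, pop, np.zeros((arr.n, 2)), extra_effects=effects)
    tad = _time_after_dose(arr)
    induction_cut = 2 * 336.0  # first two dosing intervals
    use = arr.obs_mask.copy()
    if not include_induction:
        use &= arr.t > induction_cut
    zero_pred = use & ~(pred_pop > 0)
    if zero_pred.any():
        warnings.warn(
            f"{int(zero_pred.sum())} observation(s) with zero population prediction excluded",
            RuntimeWarning,
            stacklevel=2,
        )
        use &= pred_pop > 0

    sims = _simulate_observations(arr, pop, n_sim, rng, effects)

    tad_f = tad[use]
    y_f = arr.y[use]
    pred_f = pred_pop[use]
    sims_f = sims[:, use]  # (n_sim, N)
    if tad_f.size == 0:
        return pd.DataFrame()

    edges = np.quantile(tad_f, np.linspace(0, 1, bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    which = np.clip(np.searchsorted(edges, tad_f, side="right") - 1, 0, bins - 1)

    pcts = (5.0, 50.0, 95.0)
    rows = []
    for b in range(bins):
        sel = which == b
        if not sel.any():
            continue
        med_pred = np.median(pred_f[sel])
        pc_obs = y_f[sel] * med_pred / pred_f[sel]
        pc_sim = sims_f[:, sel] * med_pred / pred_f[sel]
        row = {
            "bin": b,
            "tad_low": float(edges[b]),
            "tad_high": float(edges[b + 1]),
            "n_obs": int(sel.sum()),
        }
        sim_pct = np.percentile(pc_sim, pcts, axis=1)  # (3, n_sim)
        for k, p in enumerate(pcts):
            lab = f"p{int(p)}"
            row[f"obs_{lab}"] = float(np.percentile(pc_obs, p))
            lo, hi = np.percentile(sim_pct[k], [2.5, 97.5])
            row[f"sim_{lab}_low"] = float(lo)
            row[f"sim_{lab}_high"] = float(hi)
        rows.append(row)
    return pd.DataFrame(rows)


def npc(
    cohort: Cohort,
    model,
    *,
    intervals: Sequence[float] = (0.5, 0.8, 0.9, 0.95),
    n_sim: int = 500,
    seed: int = 0,
    include_induction: bool = True,
) -> pd.DataFrame:
    """Numerical predictive check: observed counts inside simulated intervals.

    For each observation the simulated predictive distribution at its design
    point defines central prediction intervals at the nominal levels; the
    fraction of observed values falling inside each interval is compared with
    the nominal level, with a 95% CI derived from the replicate-by-replicate
    simulated fractions.  Rows falling outside their CI are flagged.
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives unstable NPC percentiles", RuntimeWarning)
    pop, effects = _as_pop(model)
    arr = CohortArrays(cohort)
    use = arr.obs_mask.copy()
    if not include_induction:
        use &= arr.t > 2 * 336.0
    if not use.any():
        return pd.DataFrame(
            columns=["interval", "n", "expected", "observed", "ci95_low", "ci95_high", "outlier"]
        )
    rng = np.random.default_rng(seed)
    sims = _simulate_observations(arr, pop, n_sim, rng, effects)[:, use]  # (S, N)
    y = arr.y[use]

    rows = []
    for p in intervals:
        lo_q, hi_q = 50 * (1 - p), 50 * (1 + p)
        lo = np.percentile(sims, lo_q, axis=0)
        hi = np.percentile(sims, hi_q, axis=0)
        obs_frac = float(np.mean((y >= lo) & (y <= hi)))
        rep_frac = ((sims >= lo) & (sims <= hi)).mean(axis=1)
        ci_lo, ci_hi = np.percentile(rep_frac, [2.5, 97.5])
        rows.append(
            {
                "interval": p,
                "n": int(y.size),
                "expected": p,
                "observed": obs_frac,
                "ci95_low": float(ci_lo),
                "ci95_high": float(ci_hi),
                "outlier": bool(obs_frac < ci_lo or obs_frac > ci_hi),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NpdeResult:
    """Normalized prediction distribution errors with calibration tests."""

    table: pd.DataFrame  # columns: id, time, npde
    mean: float
    variance: float
    p_mean: float  # t-test of mean 0
    p_variance: float  # chi-square test of variance 1

    @property
    def values(self) -> np.ndarray:
        return self.table["npde"].to_numpy()


def npde(
    cohort: Cohort,
    model,
    *,
    n_sim: int = 1000,
    seed: int = 0,
) -> NpdeResult:
    """Normalized prediction distribution errors.

    Per subject, ``n_sim`` replicate observation vectors are simulated; the
    observed and simulated vectors are decorrelated with the simulated mean
    and Cholesky factor of the simulated covariance (ridge-regularized with a
    warning when singular); each decorrelated observation is rank-transformed
    against its decorrelated simulations -- midrank for ties, mapped to
    ``(count + 0.5*ties + 0.5) / (n_sim + 1)`` -- then to a normal quantile.
    Under a correct model the NPDE are standard normal; the summary reports
    mean, variance and the corresponding calibration p-values.
    """
    pop, effects = _as_pop(model)
    arr = CohortArrays(cohort)
    rng = np.random.default_rng(seed)
    sims = _simulate_observations(arr, pop, n_sim, rng, effects)  # (S, n, m)

    rows = []
    warned = False
    for i in range(arr.n):
        m_i = int(arr.obs_mask[i].sum())
        if m_i == 0:
            continue
        cols = np.where(arr.obs_mask[i])[0]
        S = sims[:, i, :][:, cols]  # (n_sim, m_i)
        y = arr.y[i, cols]
        E = S.mean(axis=0)
        if m_i == 1:
            y_star = (y - E) / max(S.std(axis=0)[0], 1e-12)
            s_star = (S - E) / max(S.std(axis=0)[0], 1e-12)
        else:
            C = np.cov(S, rowvar=False)
            ridge = 0.0
            for _ in range(8):
                try:
                    L = np.linalg.cholesky(C + ridge * np.eye(m_i))
                    break
                except np.linalg.LinAlgError:
                    ridge = max(ridge * 10, 1e-10 * max(np.trace(C) / m_i, 1e-12))
            else:  # pragma: no cover
                raise np.linalg.LinAlgError("simulated covariance irreparably singular")
            if ridge and not warned:
                warnings.warn(
                    "singular simulated covariance ridge-regularized in NPDE",
                    RuntimeWarning,
                    stacklevel=2,
                )
                warned = True
            y_star = np.linalg.solve(L, y - E)
            s_star = np.linalg.solve(L, (S - E).T).T
        below = (s_star < y_star).sum(axis=0)
        ties = (s_star == y_star).sum(axis=0)
        u = (below + 0.5 * ties + 0.5) / (n_sim + 1)
        z = stats.norm.ppf(u)
        for k, j in enumerate(cols):
            rows.append({"id": arr.ids[i], "time": float(arr.t[i, j]), "npde": float(z[k])})

    table = pd.DataFrame(rows)
    vals = table["npde"].to_numpy()
    n = len(vals)
    mean = float(vals.mean())
    var = float(vals.var(ddof=1)) if n > 1 else math.nan
    t_stat = mean / math.sqrt(var / n) if n > 1 and var > 0 else math.nan
    p_mean = float(2 * stats.t.sf(abs(t_stat), df=n - 1)) if n > 1 else math.nan
    if n > 1:
        chi = (n - 1) * var
        p_var = float(2 * min(stats.chi2.cdf(chi, n - 1), stats.chi2.sf(chi, n - 1)))
    else:
        p_var = math.nan
    return NpdeResult(table=table, mean=mean, variance=var, p_mean=p_mean, p_variance=p_var)


def plot_pcvpc(table: pd.DataFrame, ax=None):
    """Plot a pcVPC table: observed percentiles with simulated 95% bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = 0.5 * (table["tad_low"] + table["tad_high"])
    for p, color in ((5, "tab:blue"), (50, "tab:red"), (95, "tab:blue")):
        ax.fill_between(
            x, table[f"sim_p{p}_low"], table[f"sim_p{p}_high"], alpha=0.25, color=color
        )
        ax.plot(x, table[f"obs_p{p}"], "-o", color=color, label=f"obs p{p}")
    ax.set_xlabel("time after previous dose (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.legend()
    return ax
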