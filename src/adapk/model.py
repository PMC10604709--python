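"""statsmodels-style front end: a model object built from data whose ``fit()``
returns a results object carrying estimates, uncertainties and diagnostics.

Typical session::

    from adapk import PopPKModel, final_parameters
    model = PopPKModel(cohort, init=final_parameters())
    res = model.fit()
    print(res.summary())
    boot = res.bootstrap(n_reps=500, seed=1)
    vpc = res.pcvpc(seed=1)
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import estimation, evaluation, impact as impact_mod
from .data import Cohort, hold_out_last, impute_covariates, read_dataset
from .population import PopulationParameters, PriorSpec, final_parameters

__all__ = ["PopPKModel", "PopPKResults"]


class PopPKModel:
    """One-compartment population PK model bound to a cohort.

    Parameters
    ----------
    cohort : Cohort
        Imputed dataset (no missing covariates).
    init : PopulationParameters, optional
        Initial values and fixed-parameter mask; defaults to the adopted
        adalimumab model (albumin exponent on CL/F, proportional error).
    priors : PriorSpec, optional
        Informative priors for MAP estimation; default noninformative.
    extra_effects : sequence of CovariateEffect, optional
        Additional covariate effects on clearance.
    """

    def __init__(
        self,
        cohort: Cohort,
        init: PopulationParameters | None = None,
        priors: PriorSpec | None = None,
        extra_effects: Sequence[estimation.CovariateEffect] = (),
    ):
        self.cohort = cohort
        self.init = init if init is not None else final_parameters()
        self.priors = priors or PriorSpec.noninformative()
        self.extra_effects = tuple(extra_effects)

    @classmethod
    def from_csv(
        cls,
        path,
        *,
        dialect: Mapping[str, str] | None = None,
        impute: bool = True,
        **kwargs,
    ) -> "PopPKModel":
        cohort = read_dataset(path, dialect=dialect)
        if impute:
            cohort = impute_covariates(cohort)
        return cls(cohort, **kwargs)

    def fit(
        self,
        *,
        fixed: Iterable[str] | None = None,
        seed: int = 0,
        maxiter: int = 300,
    ) -> "PopPKResults":
        fit = estimation.fit_population(
            self.cohort,
            self.init,
            self.priors,
            fixed=fixed,
            extra_effects=self.extra_effects,
            seed=seed,
            maxiter=maxiter,
        )
        return PopPKResults(self, fit)

    def evaluate(self, params: PopulationParameters) -> float:
        """Laplace OFV of given parameters on this model's cohort (no fitting)."""
        return estimation.laplace_ofv(
            self.cohort, params, extra_effects=self.extra_effects
        )


class PopPKResults:
    """Fit results: estimates, uncertainties, diagnostics and evaluation hooks."""

    def __init__(self, model: PopPKModel, fit: estimation.FitResult):
        self.model = model
        self._fit = fit

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> PopulationParameters:
        return self._fit.estimates

    @property
    def extra_effects(self):
        return self._fit.extra_effects

    @property
    def estimates(self) -> PopulationParameters:  # FitResult-compatible alias
        return self._fit.estimates

    @property
    def ofv(self) -> float:
        return self._fit.ofv

    @property
    def rse(self) -> Mapping[str, float]:
        return self._fit.rse

    @property
    def se(self) -> Mapping[str, float]:
        return self._fit.se

    @property
    def conf_int(self) -> Mapping[str, tuple[float, float]]:
        return self._fit.ci

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def ebes(self):
        return self._fit.ebes

    @property
    def fit_result(self) -> estimation.FitResult:
        return self._fit

    def summary(self) -> str:
        """Human-readable fit summary table."""
        f = self._fit
        lines = [
            "Population PK fit (one-compartment, first-order absorption; Laplace)",
            f"  subjects: {f.n_subjects}   observations: {f.n_obs}",
            f"  OFV (-2LL): {f.ofv:.3f}   converged: {f.converged}",
            "",
        ]
        frame = f.summary_frame()
        if len(frame):
            lines.append(frame.to_string(float_format=lambda v: f"{v:.4g}"))
        fixed = sorted(f.estimates.fixed)
        lines.append("")
        lines.append(
            "  fixed: "
            + ", ".join(f"{n}={f.estimates.get(n):.4g}" for n in fixed if n != "err_add")
        )
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        return self._fit.summary_frame()

    # -- resampling and evaluation ----------------------------------------
    def bootstrap(self, n_reps: int = 500, seed: int = 0) -> estimation.BootstrapResult:
        return estimation.bootstrap_fit(
            self.model.cohort,
            self.params,
            self.model.priors,
            n_reps=n_reps,
            seed=seed,
            extra_effects=self.extra_effects,
        )

    def loo_predictions(self, cohort: Cohort | None = None):
        """Leave-last-out prediction pairs (cohort defaults to the fit data)."""
        cohort = cohort or self.model.cohort
        if not any(o.held_out for s in cohort for o in s.observations):
            cohort = hold_out_last(cohort)
        return evaluation.leave_last_out_predict(cohort, self._fit)

    def performance(self, cohort: Cohort | None = None, n_reps: int = 500, seed: int = 0):
        pairs = self.loo_predictions(cohort)
        summaries, _ = evaluation.bootstrap_performance(
            cohort or hold_out_last(self.model.cohort),
            {"model": self._fit},
            n_reps=n_reps,
            seed=seed,
        )
        return summaries["model"]

    def pcvpc(self, **kwargs) -> pd.DataFrame:
        return evaluation.pcvpc(self.model.cohort, self._fit, **kwargs)

    def npc(self, **kwargs) -> pd.DataFrame:
        return evaluation.npc(self.model.cohort, self._fit, **kwargs)

    def npde(self, **kwargs) -> evaluation.NpdeResult:
        return evaluation.npde(self.model.cohort, self._fit, **kwargs)

    def impact(self, cohort: Cohort | None = None, **kwargs):
        pairs = self.loo_predictions(cohort)
        return impact_mod.bootstrap_impact(pairs, **kwargs)

    def plot_pcvpc(self, ax=None, **kwargs):
        return evaluation.plot_pcvpc(self.pcvpc(**kwargs), ax=ax)

    def __repr__(self) -> str:
        return (
            f"<PopPKResults ofv={self.ofv:.2f} converged={self.converged} "
            f"n={self._fit.n_subjects}>"
        )
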