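"""Population-level parameterization: fixed effects, random effects, residual
error and prior specifications for maximum-a-posteriori estimation.

Conventions
-----------
* Interindividual variability (IIV) is lognormal; ``omega_cl`` / ``omega_v``
  are the standard deviations of the log-scale random effects (Monolix
  reporting convention).
* The residual error SD is ``a + b * f`` (Monolix "combined1"); the
  proportional model is the ``a = 0`` special case.
* The reported objective scale is OFV = -2 log-likelihood.
* Priors for MAP estimation are lognormal on positive parameters with log-SD
  equal to the relative standard error (RSE ~ CV for small RSE); sign-free
  parameters (the albumin exponent) take a normal prior with SD = |mean|*RSE.
  The penalty keeps only the quadratic kernel, so a noninformative prior
  (huge RSE) contributes exactly nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .data import Subject
from .structural import concentration, individual_params

__all__ = [
    "PopulationParameters",
    "RandomEffects",
    "PriorSpec",
    "PriorEntry",
    "residual_model",
    "individual_loglik",
    "prior_penalty",
    "reference_parameters",
    "final_parameters",
    "reference_priors",
    "PARAMETER_NAMES",
    "LOG_SCALE_PARAMS",
]

PARAMETER_NAMES = (
    "cl_pop",
    "v_pop",
    "ka_pop",
    "cov_aaa",
    "cov_alb",
    "omega_cl",
    "omega_v",
    "err_add",
    "err_prop",
)

# parameters estimated on the log scale (strictly positive)
LOG_SCALE_PARAMS = frozenset(
    {"cl_pop", "v_pop", "ka_pop", "omega_cl", "omega_v", "err_add", "err_prop"}
)


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, IIV standard deviations and residual-error coefficients.

    ``fixed`` lists parameters held at their value during estimation; the
    absorption constant and the anti-drug-antibody effect are fixed by default
    (trough-only data carry no absorption-phase information, and too few
    antibody-positive patients exist to estimate their clearance shift).
    """

    cl_pop: float  # L/h
    v_pop: float  # L
    ka_pop: float = 0.00625  # 1/h
    cov_aaa: float = 4.5  # fractional clearance increase when AAA-positive
    cov_alb: float = 0.0  # albumin power exponent on CL/F
    m_alb: float = 3.77  # centering albumin, g/dL
    omega_cl: float = 0.1  # SD of log CL random effect
    omega_v: float = 0.1  # SD of log V random effect
    err_add: float = 0.0  # additive residual SD, mg/L
    err_prop: float = 0.0  # proportional residual coefficient
    fixed: frozenset = frozenset({"ka_pop", "cov_aaa"})

    def __post_init__(self) -> None:
        for name in ("cl_pop", "v_pop", "ka_pop", "omega_cl", "omega_v", "m_alb"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.err_add < 0 or self.err_prop < 0:
            raise ValueError("residual error coefficients must be >= 0")
        if self.err_add == 0 and self.err_prop == 0:
            raise ValueError("residual error is degenerate: err_add and err_prop both 0")
        if self.cov_aaa <= -1:
            raise ValueError("cov_aaa must exceed -1 (clearance must stay positive)")
        unknown = set(self.fixed) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")

    def get(self, name: str) -> float:
        return getattr(self, name)

    def with_values(self, **updates) -> "PopulationParameters":
        return replace(self, **updates)


@dataclass(frozen=True)
class RandomEffects:
    """Log-scale deviations of one subject's CL and V from the typical values."""

    eta_cl: float = 0.0
    eta_v: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eta_cl) and np.isfinite(self.eta_v)):
            raise ValueError("random effects must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta_cl, self.eta_v], dtype=float)


@dataclass(frozen=True)
class PriorEntry:
    prior_mean: float
    prior_rse: float  # fraction, e.g. 0.10 for 10%
    informative: bool = True

    def __post_init__(self) -> None:
        if self.informative and not (self.prior_rse > 0):
            raise ValueError("informative prior requires prior_rse > 0")


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior means and uncertainties for MAP estimation."""

    entries: Mapping[str, PriorEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.entries) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"priors reference unknown parameter(s): {sorted(unknown)}")

    def informative(self) -> dict[str, PriorEntry]:
        return {k: v for k, v in self.entries.items() if v.informative}

    @classmethod
    def noninformative(cls) -> "PriorSpec":
        return cls(entries={})


def residual_model(pred, a: float, b: float):
    """Observation SD (mg/L) for prediction ``pred``: ``a + b * pred``.

    ``a`` is the additive floor (mg/L), ``b`` the proportional coefficient.
    ``a = b = 0`` is rejected (degenerate likelihood).  ``a = 0`` with
    ``pred = 0`` yields SD 0, which callers must flag as a zero-variance
    observation before using it in a Gaussian density.
    """
    if a == 0 and b == 0:
        raise ValueError("degenerate residual model: a and b both zero")
    if a < 0 or b < 0:
        raise ValueError("residual error coefficients must be >= 0")
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("prediction must be >= 0")
    out = a + b * pred
    return float(out) if out.ndim == 0 else out


_LOG_2PI = math.log(2.0 * math.pi)


def individual_loglik(
    subject: Subject,
    pop: PopulationParameters,
    eta: RandomEffects,
    *,
    use_held_out: bool = True,
) -> float:
    """Joint log-density of one subject's data and random effects.

    Sum over used observations of the Gaussian log-density with mean equal to
    the structural prediction under ``individual_params(pop, eta, ...)`` and SD
    from :func:`residual_model`, plus the log-density of ``eta`` under
    ``N(0, diag(omega_cl^2, omega_v^2))``.  With ``use_held_out=False`` the
    observations flagged ``held_out`` are excluded from the data term (the
    leave-last-out convention).
    """
    if subject.albumin is None or subject.aaa is None:
        raise ValueError(f"subject {subject.id}: covariates missing; impute first")
    params = individual_params(pop, eta, albumin=subject.albumin, aaa=subject.aaa)
    ll = 0.0
    for obs in subject.observations:
        if obs.held_out and not use_held_out:
            continue
        f = concentration(params, subject.doses, obs.time)
        sd = residual_model(f, pop.err_add, pop.err_prop)
        if sd <= 0:
            raise ValueError(
                f"subject {subject.id}: zero residual SD at t={obs.time} h "
                "(additive-error-free model with zero prediction)"
            )
        ll += -0.5 * _LOG_2PI - math.log(sd) - 0.5 * ((obs.concentration - f) / sd) ** 2
    for e, w in ((eta.eta_cl, pop.omega_cl), (eta.eta_v, pop.omega_v)):
        ll += -0.5 * _LOG_2PI - math.log(w) - 0.5 * (e / w) ** 2
    return ll


def prior_penalty(pop: PopulationParameters, priors: PriorSpec) -> float:
    """-2 log prior kernel summed over informative parameters.

    For a positive parameter with informative prior (mean ``m``, RSE ``r``)
    the contribution is ``((log theta - log m)/r)^2`` (lognormal kernel); for
    the sign-free albumin exponent it is ``((theta - m)/(|m| r))^2``.
    Normalizing constants are dropped so the contribution of each parameter
    vanishes in the noninformative (large-RSE) limit and is minimized exactly
    at the prior mean.  A parameter that is both fixed and informative is a
    configuration error.
    """
    total = 0.0
    for name, entry in priors.informative().items():
        if name in pop.fixed:
            raise ValueError(
                f"informative prior on fixed parameter {name!r}; unfix it or drop the prior"
            )
        theta = pop.get(name)
        if name in LOG_SCALE_PARAMS:
            if theta <= 0 or entry.prior_mean <= 0:
                raise ValueError(f"lognormal prior on {name} requires positive values")
            z = (math.log(theta) - math.log(entry.prior_mean)) / entry.prior_rse
        else:
            sd = abs(entry.prior_mean) * entry.prior_rse
            if sd == 0:
                raise ValueError(f"normal prior on {name} has zero SD")
            z = (theta - entry.prior_mean) / sd
        total += z * z
    return total


def reference_parameters() -> PopulationParameters:
    """The literature (reference) model: combined error, no albumin effect."""
    return PopulationParameters(
        cl_pop=0.0175,
        v_pop=13.5,
        ka_pop=0.00625,
        cov_aaa=4.5,
        cov_alb=0.0,
        m_alb=3.77,
        omega_cl=0.65,
        omega_v=0.48,
        err_add=1.8,
        err_prop=0.15,
        fixed=frozenset({"ka_pop", "cov_aaa", "cov_alb"}),
    )


def final_parameters() -> PopulationParameters:
    """The adopted model: albumin exponent on CL/F, proportional error."""
    return PopulationParameters(
        cl_pop=0.0312,
        v_pop=7.76,
        ka_pop=0.00625,
        cov_aaa=4.5,
        cov_alb=-2.33,
        m_alb=3.77,
        omega_cl=0.667,
        omega_v=0.477,
        err_add=0.0,
        err_prop=0.547,
        fixed=frozenset({"ka_pop", "cov_aaa", "err_add"}),
    )


def reference_priors() -> PriorSpec:
    """Informative priors built from the reference model's estimates and RSEs."""
    return PriorSpec(
        entries={
            "cl_pop": PriorEntry(0.0175, 0.09),
            "v_pop": PriorEntry(13.5, 0.10),
            "omega_cl": PriorEntry(0.65, 0.10),
            "omega_v": PriorEntry(0.48, 0.19),
            "err_prop": PriorEntry(0.15, 0.16),
            "err_add": PriorEntry(1.8, 0.08),
        }
    )
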