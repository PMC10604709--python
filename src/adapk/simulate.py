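"""Virtual IBD cohorts emulating the therapeutic-drug-monitoring study design.

The study population this generator mimics: 54 adult IBD patients on
subcutaneous adalimumab -- 160/80 mg induction at weeks 0/2 (a small fraction
on 80/40), 40 mg every other week thereafter -- with sparse trough sampling
(2-4 troughs per patient, ~148 samples in all, a minority during induction),
serum albumin spanning roughly 2-5 g/dL and ~17% anti-drug-antibody
prevalence.  Each subject's clearance and volume carry lognormal
interindividual variability, and observations receive combined/proportional
residual noise consistent with the likelihood's ``SD = a + b*f`` convention.

A ``rich_design`` variant replaces sparse troughs with a fixed 8-point
schedule including absorption-phase samples and samples albumin uniformly
over its range: that design exists for identifiability/recovery experiments,
not to mimic the clinic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Cohort, DoseEvent, Observation, Subject
from .population import PopulationParameters
from .structural import profile

__all__ = ["DesignSpec", "generate_cohort", "apply_loq"]

# default rich sampling grid (hours): absorption-phase and trough-like times
RICH_TIMES = (24.0, 72.0, 168.0, 335.0, 420.0, 520.0, 671.0, 1007.0)


@dataclass(frozen=True)
class DesignSpec:
    """Study-design knobs for the synthetic cohort generator.

    Defaults reproduce the monitored IBD cohort: 54 subjects, 160/80 mg
    induction (weeks 0/2) with 2/54 on the 80/40 variant, 40 mg q2w
    maintenance, 2-4 pre-dose troughs per subject with ~25% of subjects
    contributing one induction-phase trough, truncated-normal albumin
    (mean 3.77, SD 0.55 g/dL, bounds 1.97-4.96) and 16.7% AAA prevalence.
    """

    n_subjects: int = 54
    induction_doses: tuple[tuple[float, float], ...] = ((0.0, 160.0), (336.0, 80.0))
    low_induction_doses: tuple[tuple[float, float], ...] = ((0.0, 80.0), (336.0, 40.0))
    low_induction_fraction: float = 2.0 / 54.0
    maintenance_amount: float = 40.0
    maintenance_interval: float = 336.0
    n_maintenance: int = 18
    n_troughs_probs: tuple[float, float, float] = (0.40, 0.45, 0.15)  # P(2), P(3), P(4)
    induction_trough_fraction: float = 0.25
    trough_jitter: float = 24.0  # troughs drawn U(0, jitter) h before a dose
    albumin_mean: float = 3.77
    albumin_sd: float = 0.55
    albumin_bounds: tuple[float, float] = (1.97, 4.96)
    albumin_uniform: bool = False
    aaa_prevalence: float = 0.167
    rich_design: bool = False
    rich_times: tuple[float, ...] = RICH_TIMES
    reporting_floor: float = 0.1  # assay lower limit of quantification, mg/L
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.aaa_prevalence <= 1):
            raise ValueError("aaa_prevalence must be in [0, 1]")
        if not (0 <= self.low_induction_fraction <= 1):
            raise ValueError("low_induction_fraction must be in [0, 1]")
        if not (0 <= self.induction_trough_fraction <= 1):
            raise ValueError("induction_trough_fraction must be in [0, 1]")
        lo, hi = self.albumin_bounds
        if not (0 < lo < hi):
            raise ValueError("albumin bounds must be ordered and positive")
        if abs(sum(self.n_troughs_probs) - 1.0) > 1e-9:
            raise ValueError("n_troughs_probs must sum to 1")
        if self.maintenance_interval <= 0 or self.maintenance_amount <= 0:
            raise ValueError("maintenance schedule must be positive")


def _draw_albumin(spec: DesignSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = spec.albumin_bounds
    if spec.albumin_uniform:
        return rng.uniform(lo, hi, size=n)
    out = np.empty(n)
    for i in range(n):  # rejection sampling from the truncated normal
        while True:
            x = rng.normal(spec.albumin_mean, spec.albumin_sd)
            if lo <= x <= hi:
                out[i] = x
                break
    return out


def _dose_schedule(spec: DesignSpec, low_variant: bool) -> list[DoseEvent]:
    base = spec.low_induction_doses if low_variant else spec.induction_doses
    doses = [DoseEvent(t, a) for t, a in base]
    t0 = max(t for t, _ in base) + spec.maintenance_interval
    for k in range(spec.n_maintenance):
        doses.append(DoseEvent(t0 + k * spec.maintenance_interval, spec.maintenance_amount))
    return doses


def generate_cohort(
    spec: DesignSpec, pop: PopulationParameters
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort and return it with a sidecar truth table.

    Per subject: albumin and AAA status drawn from the design distributions,
    random effects from N(0, diag(omega^2)), the dosing schedule from the
    design, trough times as jittered pre-dose samples of distinct maintenance
    doses (plus an induction trough for a fraction of subjects), and
    observations ``y = f + (a + b*f) * eps`` clamped from below at the assay
    reporting floor (``spec.reporting_floor``, default the 0.1 mg/L lower
    limit of quantification; set 0 for a bare non-negativity floor, at the
    price of a likelihood that is unbounded at exact zeros).  The truth table
    (one row per subject: eta values, individual CL and V, covariates) is
    returned separately and never embedded in the dataset itself.

    Reproducible bit-exactly from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    albumin = _draw_albumin(spec, rng, n)
    aaa = (rng.random(n) < spec.aaa_prevalence).astype(int)
    eta = rng.normal(0.0, 1.0, size=(n, 2)) * np.array([pop.omega_cl, pop.omega_v])
    low_variant = rng.random(n) < spec.low_induction_fraction

    subjects = []
    truth_rows = []
    for i in range(n):
        doses = _dose_schedule(spec, bool(low_variant[i]))
        last_induction_time = max(t for t, _ in (
            spec.low_induction_doses if low_variant[i] else spec.induction_doses
        ))
        maintenance_times = [d.time for d in doses if d.time > last_induction_time]

        if spec.rich_design:
            times = list(spec.rich_times)
            is_trough = [False] * len(times)
        else:
            k = 2 + int(rng.choice(3, p=spec.n_troughs_probs))
            times = []
            if rng.random() < spec.induction_trough_fraction:
                # induction trough: just before the week-2 dose
                times.append(doses[1].time - rng.uniform(0.0, spec.trough_jitter))
                k -= 1
            chosen = rng.choice(len(maintenance_times), size=min(k, len(maintenance_times)), replace=False)
            for c in sorted(chosen):
                times.append(maintenance_times[c] - rng.uniform(0.0, spec.trough_jitter))
            is_trough = [True] * len(times)
        order = np.argsort(times)
        times = [times[j] for j in order]
        is_trough = [is_trough[j] for j in order]

        cl_typ = (
            pop.cl_pop
            * (1.0 + aaa[i] * pop.cov_aaa)
            * (albumin[i] / pop.m_alb) ** pop.cov_alb
        )
        cl_i = cl_typ * np.exp(eta[i, 0])
        v_i = pop.v_pop * np.exp(eta[i, 1])
        dose_t = np.array([[d.time for d in doses]])
        dose_a = np.array([[d.amount for d in doses]])
        f = profile(np.array([cl_i]), np.array([v_i]), pop.ka_pop, dose_t, dose_a,
                    np.array([times]))[0]
        eps = rng.normal(0.0, 1.0, size=len(times))
        # the assay never reports below its quantification limit: clamping
        # there (not at 0) also keeps the proportional-error likelihood
        # bounded, which exact zeros would break
        y = np.maximum(f + (pop.err_add + pop.err_prop * f) * eps, spec.reporting_floor)

        sid = f"S{i + 1:03d}"
        obs = tuple(
            Observation(time=float(t), concentration=float(c), is_trough=bool(tr))
            for t, c, tr in zip(times, y, is_trough)
        )
        subjects.append(
            Subject(
                id=sid,
                doses=tuple(doses),
                observations=obs,
                albumin=float(albumin[i]),
                aaa=int(aaa[i]),
                albumin_samples=tuple(float(albumin[i]) for _ in obs),
                aaa_samples=tuple(float(aaa[i]) for _ in obs),
            )
        )
        truth_rows.append(
            {
                "id": sid,
                "eta_cl": eta[i, 0],
                "eta_v": eta[i, 1],
                "cl": cl_i,
                "v": v_i,
                "albumin": albumin[i],
                "aaa": aaa[i],
                "low_induction": bool(low_variant[i]),
            }
        )

    cohort = Cohort(
        subjects=tuple(subjects),
        meta={
            "generator": "adapk.simulate.generate_cohort",
            "seed": spec.seed,
            "n_subjects": n,
            "rich_design": spec.rich_design,
            "assay_range_mg_L": (0.1, 16.0),
        },
    )
    return cohort, pd.DataFrame(truth_rows).set_index("id")


def apply_loq(cohort: Cohort, loq: float = 0.1, policy: str = "keep") -> Cohort:
    """Handle observations below the assay's lower limit of quantification.

    ``policy`` is ``"keep"`` (use values as reported -- the main analysis
    convention), ``"drop"`` (remove sub-LOQ observations) or ``"floor"``
    (set them to the LOQ).
    """
    if policy not in ("keep", "drop", "floor"):
        raise ValueError(f"unknown LOQ policy {policy!r}")
    if policy == "keep":
        return cohort
    from dataclasses import replace as _replace

    new_subjects = []
    for s in cohort:
        if policy == "drop":
            obs = tuple(o for o in s.observations if o.concentration >= loq)
        else:
            obs = tuple(
                _replace(o, concentration=max(o.concentration, loq))
                for o in s.observations
            )
        new_subjects.append(_replace(s, observations=obs))
    meta = dict(cohort.meta)
    meta["loq_policy"] = policy
    return Cohort(subjects=tuple(new_subjects), meta=meta)
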