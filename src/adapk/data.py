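"""Longitudinal pharmacokinetic datasets in a NONMEM/Monolix-style CSV dialect.

The in-memory containers mirror the usual therapeutic-drug-monitoring layout:
one :class:`Subject` per patient carrying an ordered dosing history, an ordered
list of trough observations and the two clearance covariates used by the
adalimumab model -- serum albumin (g/dL) and anti-adalimumab-antibody (AAA)
status.  The CSV dialect is the conventional one: columns ``ID, TIME, AMT, DV,
EVID, ALB, AAA`` with ``EVID=1`` dose rows (``AMT`` set, ``DV`` empty) and
``EVID=0`` observation rows (``DV`` set, ``AMT`` empty).  Times are hours since
the first dose; a dataset declaring any other time unit is rejected.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DoseEvent",
    "Observation",
    "Subject",
    "Cohort",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "impute_covariates",
    "hold_out_last",
]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "ALB", "AAA")


class DatasetFormatError(ValueError):
    """The file does not conform to the expected CSV dialect."""


class DatasetValidationError(ValueError):
    """The file parses but violates a dataset invariant."""


def _is_missing(token: str | None) -> bool:
    return token is None or token.strip() in ("", ".", "NA", "NaN", "nan")


@dataclass(frozen=True)
class DoseEvent:
    """A single subcutaneous dose: ``amount`` mg administered at ``time`` h."""

    time: float
    amount: float
    route: str = "SC"

    def __post_init__(self) -> None:
        if not (self.time >= 0):
            raise DatasetValidationError(f"dose time must be >= 0, got {self.time}")
        if not (self.amount > 0):
            raise DatasetValidationError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class Observation:
    """A measured drug concentration (mg/L) at ``time`` h.

    ``held_out`` marks the chronologically last trough of a subject when the
    leave-last-out evaluation has been prepared with :func:`hold_out_last`.
    """

    time: float
    concentration: float
    is_trough: bool = True
    held_out: bool = False

    def __post_init__(self) -> None:
        if not (self.time >= 0):
            raise DatasetValidationError(f"observation time must be >= 0, got {self.time}")
        if not (self.concentration >= 0):
            raise DatasetValidationError(
                f"concentration must be >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class Subject:
    """One patient: dosing history, observations and clearance covariates.

    ``albumin`` / ``aaa`` are the subject-level covariate values used by the
    model (covariates are treated as constant per subject).  ``albumin_samples``
    and ``aaa_samples`` keep the raw per-observation-row values (``None`` where
    the row was missing) so that per-patient mean imputation can be applied.
    ``covariates`` holds any extra per-subject covariates (e.g. body weight)
    used only by the covariate-search machinery.
    """

    id: str
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]
    albumin: float | None = None
    aaa: int | None = None
    albumin_samples: tuple[float | None, ...] = ()
    aaa_samples: tuple[float | None, ...] = ()
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.albumin is not None and not (self.albumin > 0):
            raise DatasetValidationError(
                f"subject {self.id}: albumin must be > 0, got {self.albumin}"
            )
        if self.aaa is not None and self.aaa not in (0, 1):
            raise DatasetValidationError(
                f"subject {self.id}: aaa must be 0 or 1, got {self.aaa}"
            )
        times = [d.time for d in self.doses]
        if times != sorted(times):
            raise DatasetValidationError(f"subject {self.id}: doses not sorted by time")
        times = [o.time for o in self.observations]
        if times != sorted(times):
            raise DatasetValidationError(
                f"subject {self.id}: observations not sorted by time"
            )
        if self.observations and not self.doses:
            raise DatasetValidationError(
                f"subject {self.id}: has observations but no dose record"
            )

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def last_observation(self) -> Observation:
        if not self.observations:
            raise DatasetValidationError(f"subject {self.id}: no observations")
        return self.observations[-1]


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of subjects plus free-form provenance metadata."""

    subjects: tuple[Subject, ...]
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise DatasetValidationError("cohort must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetValidationError(f"duplicate subject ids: {dupes}")

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)


def _parse_float(token: str, line: int, col: str, errors: list[str]) -> float:
    try:
        return float(token)
    except ValueError:
        errors.append(f"line {line}: column {col} is not numeric: {token!r}")
        return math.nan


def read_dataset(path, dialect: Mapping[str, str] | None = None) -> Cohort:
    """Read a NONMEM/Monolix-style CSV into a :class:`Cohort`.

    Parameters
    ----------
    path : path-like
        CSV file with header ``ID, TIME, AMT, DV, EVID, ALB, AAA`` (``MDV``
        optional and ignored except for consistency).  TIME is hours.
    dialect : mapping, optional
        Remaps standard column names to the file's actual names, e.g.
        ``{"ID": "subject"}``.  A ``"time_unit"`` entry other than ``"h"`` /
        ``"hours"`` is rejected.

    Raises
    ------
    DatasetFormatError
        Missing mandatory columns or an unsupported time unit.
    DatasetValidationError
        Malformed rows (reported with line numbers), negative TIME/AMT,
        unknown EVID, or a subject with observations but no dose.
    """
    dialect = dict(dialect or {})
    unit = str(dialect.pop("time_unit", "hours")).lower()
    if unit not in ("h", "hr", "hrs", "hour", "hours"):
        raise DatasetFormatError(f"unsupported time unit {unit!r}; times must be hours")
    colmap = {std: dialect.get(std, std) for std in REQUIRED_COLUMNS}

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [std for std, actual in colmap.items() if actual not in header]
        if missing:
            raise DatasetFormatError(
                f"missing mandatory column(s): {', '.join(missing)} (header: {header})"
            )
        rows = list(reader)

    errors: list[str] = []
    # accumulate per-subject rows in file order
    per_subject: dict[str, dict[str, list]] = {}
    order: list[str] = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        sid = (row.get(colmap["ID"]) or "").strip()
        if not sid:
            errors.append(f"line {i}: empty ID")
            continue
        if sid not in per_subject:
            per_subject[sid] = {"doses": [], "obs": [], "alb": [], "aaa": []}
            order.append(sid)
        rec = per_subject[sid]

        t_tok = row.get(colmap["TIME"], "")
        evid_tok = row.get(colmap["EVID"], "")
        if _is_missing(t_tok) or _is_missing(evid_tok):
            errors.append(f"line {i}: TIME and EVID are mandatory")
            continue
        t = _parse_float(t_tok, i, "TIME", errors)
        if math.isnan(t):
            continue
        if t < 0:
            errors.append(f"line {i}: negative TIME {t}")
            continue
        evid_f = _parse_float(evid_tok, i, "EVID", errors)
        if math.isnan(evid_f):
            continue
        evid = int(evid_f)
        if evid not in (0, 1):
            errors.append(f"line {i}: EVID must be 0 or 1, got {evid}")
            continue

        alb_tok = row.get(colmap["ALB"], "")
        aaa_tok = row.get(colmap["AAA"], "")
        alb = None if _is_missing(alb_tok) else _parse_float(alb_tok, i, "ALB", errors)
        aaa = None if _is_missing(aaa_tok) else _parse_float(aaa_tok, i, "AAA", errors)

        if evid == 1:
            amt_tok = row.get(colmap["AMT"], "")
            if _is_missing(amt_tok):
                errors.append(f"line {i}: dose row (EVID=1) with empty AMT")
                continue
            amt = _parse_float(amt_tok, i, "AMT", errors)
            if math.isnan(amt):
                continue
            if amt <= 0:
                errors.append(f"line {i}: dose amount must be > 0, got {amt}")
                continue
            rec["doses"].append((t, amt))
        else:
            dv_tok = row.get(colmap["DV"], "")
            if _is_missing(dv_tok):
                errors.append(f"line {i}: observation row (EVID=0) with empty DV")
                continue
            dv = _parse_float(dv_tok, i, "DV", errors)
            if math.isnan(dv):
                continue
            if dv < 0:
                errors.append(f"line {i}: negative concentration {dv}")
                continue
            rec["obs"].append((t, dv))
            rec["alb"].append(alb)
            rec["aaa"].append(aaa)

    if errors:
        raise DatasetValidationError(
            "malformed dataset rows:\n  " + "\n  ".join(errors)
        )

    subjects = []
    for sid in order:
        rec = per_subject[sid]
        if rec["obs"] and not rec["doses"]:
            raise DatasetValidationError(
                f"subject {sid}: has observations but no dose record"
            )
        # stable sort by time, preserving file order within ties
        dose_idx = sorted(range(len(rec["doses"])), key=lambda k: rec["doses"][k][0])
        obs_idx = sorted(range(len(rec["obs"])), key=lambda k: rec["obs"][k][0])
        doses = tuple(DoseEvent(*rec["doses"][k]) for k in dose_idx)
        obs = tuple(Observation(*rec["obs"][k]) for k in obs_idx)
        alb_samples = tuple(rec["alb"][k] for k in obs_idx)
        aaa_samples = tuple(rec["aaa"][k] for k in obs_idx)
        alb_present = [a for a in alb_samples if a is not None]
        aaa_present = [a for a in aaa_samples if a is not None]
        albumin = sum(alb_present) / len(alb_present) if alb_present else None
        aaa = (1 if any(a > 0 for a in aaa_present) else 0) if aaa_present else None
        subjects.append(
            Subject(
                id=sid,
                doses=doses,
                observations=obs,
                albumin=albumin,
                aaa=aaa,
                albumin_samples=alb_samples,
                aaa_samples=aaa_samples,
            )
        )
    return Cohort(subjects=tuple(subjects), meta={"source": str(path), "assay_range_mg_L": (0.1, 16.0)})


def _fmt(x: float) -> str:
    if x is None:
        return ""
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_dataset(cohort: Cohort, path) -> None:
    """Write a :class:`Cohort` in the same CSV dialect :func:`read_dataset` reads.

    Dose rows come first at equal times; covariates are written on every row
    from the subject-level values.  Reading the file back yields a cohort with
    identical data values.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REQUIRED_COLUMNS)
        for s in cohort:
            events: list[tuple[float, int, list]] = []
            for d in s.doses:
                events.append((d.time, 0, [s.id, _fmt(d.time), _fmt(d.amount), "", "1"]))
            for o in s.observations:
                events.append((o.time, 1, [s.id, _fmt(o.time), "", _fmt(o.concentration), "0"]))
            events.sort(key=lambda e: (e[0], e[1]))
            alb = "" if s.albumin is None else _fmt(s.albumin)
            aaa = "" if s.aaa is None else _fmt(s.aaa)
            for _, _, fields in events:
                w.writerow(fields + [alb, aaa])


def impute_covariates(cohort: Cohort) -> Cohort:
    """Fill missing albumin/AAA values by per-patient means, then grand means.

    A subject with at least one recorded albumin value gets that subject's
    mean; a subject with none gets the mean of the other subjects' per-subject
    means.  AAA is handled with the same rule, except that the subject-level
    status is binary: positive if any recorded row is positive, and the grand
    mean is thresholded at 0.5 for fully missing subjects.  Idempotent; never
    alters non-missing values.

    Raises
    ------
    DatasetValidationError
        If a covariate is missing for every subject in the cohort.
    """
    subj_alb_means = []
    subj_aaa_vals = []
    for s in cohort:
        alb_present = [a for a in s.albumin_samples if a is not None]
        if alb_present:
            subj_alb_means.append(sum(alb_present) / len(alb_present))
        elif s.albumin is not None:
            subj_alb_means.append(s.albumin)
        aaa_present = [a for a in s.aaa_samples if a is not None]
        if aaa_present:
            subj_aaa_vals.append(1.0 if any(a > 0 for a in aaa_present) else 0.0)
        elif s.aaa is not None:
            subj_aaa_vals.append(float(s.aaa))

    if not subj_alb_means:
        raise DatasetValidationError("albumin missing for every subject; nothing to impute from")
    if not subj_aaa_vals:
        raise DatasetValidationError("AAA missing for every subject; nothing to impute from")
    grand_alb = sum(subj_alb_means) / len(subj_alb_means)
    grand_aaa = sum(subj_aaa_vals) / len(subj_aaa_vals)

    new_subjects = []
    for s in cohort:
        alb_present = [a for a in s.albumin_samples if a is not None]
        if alb_present:
            mean_alb = sum(alb_present) / len(alb_present)
        elif s.albumin is not None:
            mean_alb = s.albumin
        else:
            mean_alb = grand_alb
        n_rows = max(len(s.albumin_samples), len(s.aaa_samples), len(s.observations))
        alb_rows = tuple(
            s.albumin_samples[k]
            if k < len(s.albumin_samples) and s.albumin_samples[k] is not None
            else mean_alb
            for k in range(n_rows)
        )
        aaa_present = [a for a in s.aaa_samples if a is not None]
        if aaa_present:
            aaa_val = 1 if any(a > 0 for a in aaa_present) else 0
        elif s.aaa is not None:
            aaa_val = int(s.aaa)
        else:
            aaa_val = 1 if grand_aaa >= 0.5 else 0
        aaa_rows = tuple(
            s.aaa_samples[k]
            if k < len(s.aaa_samples) and s.aaa_samples[k] is not None
            else float(aaa_val)
            for k in range(n_rows)
        )
        new_subjects.append(
            replace(
                s,
                albumin=mean_alb,
                aaa=aaa_val,
                albumin_samples=alb_rows,
                aaa_samples=aaa_rows,
            )
        )
    meta = dict(cohort.meta)
    meta["covariates_imputed"] = True
    return Cohort(subjects=tuple(new_subjects), meta=meta)


def hold_out_last(cohort: Cohort) -> Cohort:
    """Flag each subject's chronologically last observation as held out.

    This prepares the leave-last-out evaluation: the flagged trough is excluded
    from empirical-Bayes estimation and then predicted.  Every subject must
    have at least two observations (the study inclusion criterion); nothing is
    deleted, exactly one observation per subject is flagged.
    """
    new_subjects = []
    for s in cohort:
        if s.n_obs < 2:
            raise DatasetValidationError(
                f"subject {s.id}: {s.n_obs} observation(s); leave-last-out requires "
                "at least two trough concentrations per subject (inclusion criterion)"
            )
        last = len(s.observations) - 1
        obs = tuple(
            replace(o, held_out=(k == last)) for k, o in enumerate(s.observations)
        )
        new_subjects.append(replace(s, observations=obs))
    meta = dict(cohort.meta)
    meta["held_out"] = "last observation per subject"
    return Cohort(subjects=tuple(new_subjects), meta=meta)
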