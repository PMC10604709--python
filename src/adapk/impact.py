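"""Clinical impact of trough forecasts against the 8-12 mg/L therapeutic window.

Trough targets drive dosing decisions: a forecast below 8 mg/L calls for dose
escalation, above 12 mg/L for de-escalation, inside the window for no change.
The impact analysis classifies each held-out observed trough and its model
forecast into the three ranges and counts, per range, true positives
(observation and forecast agree on the range) and false positives (the
forecast lands in the range, the observation does not), with subject-level
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import PredictionPair

__all__ = ["classify_range", "impact_table", "bootstrap_impact", "ImpactTable"]

RANGES = ("below", "within", "above")


def classify_range(c: float, low: float = 8.0, high: float = 12.0) -> str:
    """Label a concentration against the therapeutic window.

    ``below`` if c < low, ``within`` if low <= c <= high (both boundaries
    belong to the window), ``above`` if c > high.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if c < low:
        return "below"
    if c <= high:
        return "within"
    return "above"


@dataclass(frozen=True)
class ImpactTable:
    """Per-range true/false-positive counts (optionally with bootstrap CIs).

    ``counts`` maps each range to ``{"tp": ..., "fp": ..., "obs_n": ...}``;
    raw integer counts live in ``counts``, bootstrap means and percentile 95%
    CIs (when computed) in ``boot_mean`` / ``ci`` keyed the same way.
    """

    counts: Mapping[str, Mapping[str, int]]
    n: int
    low: float = 8.0
    high: float = 12.0
    boot_mean: Mapping[str, Mapping[str, float]] | None = None
    ci: Mapping[str, Mapping[str, tuple[float, float]]] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in RANGES:
            row = {"range": r, **self.counts[r]}
            if self.boot_mean is not None:
                for cell in ("tp", "fp"):
                    row[f"{cell}_boot_mean"] = self.boot_mean[r][cell]
                    lo, hi = self.ci[r][cell]
                    row[f"{cell}_ci95_low"] = lo
                    row[f"{cell}_ci95_high"] = hi
            rows.append(row)
        return pd.DataFrame(rows).set_index("range")


def _count(obs_lab: np.ndarray, pred_lab: np.ndarray) -> dict[str, dict[str, int]]:
    out = {}
    for r in RANGES:
        in_obs = obs_lab == r
        in_pred = pred_lab == r
        out[r] = {
            "tp": int(np.sum(in_obs & in_pred)),
            "fp": int(np.sum(~in_obs & in_pred)),
            "obs_n": int(np.sum(in_obs)),
        }
    return out


def impact_table(
    pairs: Sequence[PredictionPair], *, low: float = 8.0, high: float = 12.0
) -> ImpactTable:
    """Tabulate true/false positives of range classification per range.

    For range R: ``tp`` counts subjects whose observed and predicted troughs
    both fall in R; ``fp`` counts predictions in R whose observation is
    elsewhere; ``obs_n`` counts observations in R (the obs_n sum over ranges
    is the number of subjects).
    """
    if not pairs:
        raise ValueError("impact_table requires at least one prediction pair")
    obs_lab = np.array([classify_range(p.y_obs, low, high) for p in pairs])
    pred_lab = np.array([classify_range(p.y_pred, low, high) for p in pairs])
    return ImpactTable(counts=_count(obs_lab, pred_lab), n=len(pairs), low=low, high=high)


def bootstrap_impact(
    pairs: Sequence[PredictionPair],
    *,
    pairs_other: Sequence[PredictionPair] | None = None,
    low: float = 8.0,
    high: float = 12.0,
    n_reps: int = 500,
    seed: int = 0,
):
    """Subject-level bootstrap of the impact table.

    Returns an :class:`ImpactTable` carrying raw counts plus bootstrap means
    and percentile 95% CIs per cell.  When ``pairs_other`` (a second model's
    pairs on the same subjects) is given, additionally returns a DataFrame of
    per-cell paired differences (model - other) with their CIs.  Reproducible
    under a fixed ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not pairs:
        raise ValueError("bootstrap_impact requires at least one prediction pair")
    n = len(pairs)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_reps, n))

    def labels(ps):
        return (
            np.array([classify_range(p.y_obs, low, high) for p in ps]),
            np.array([classify_range(p.y_pred, low, high) for p in ps]),
        )

    obs_lab, pred_lab = labels(pairs)
    base = impact_table(pairs, low=low, high=high)

    def rep_counts(obs_l, pred_l):
        # (n_reps, n_ranges, 2) tp/fp counts per replicate
        out = np.empty((n_reps, len(RANGES), 2))
        for k, r in enumerate(RANGES):
            in_obs = (obs_l == r)[idx]
            in_pred = (pred_l == r)[idx]
            out[:, k, 0] = (in_obs & in_pred).sum(axis=1)
            out[:, k, 1] = (~in_obs & in_pred).sum(axis=1)
        return out

    reps = rep_counts(obs_lab, pred_lab)
    boot_mean = {}
    ci = {}
    for k, r in enumerate(RANGES):
        boot_mean[r] = {"tp": float(reps[:, k, 0].mean()), "fp": float(reps[:, k, 1].mean())}
        ci[r] = {
            "tp": tuple(np.percentile(reps[:, k, 0], [2.5, 97.5])),
            "fp": tuple(np.percentile(reps[:, k, 1], [2.5, 97.5])),
        }
    table = ImpactTable(
        counts=base.counts, n=n, low=low, high=high, boot_mean=boot_mean, ci=ci
    )
    if pairs_other is None:
        return table

    if len(pairs_other) != n or any(
        a.subject_id != b.subject_id for a, b in zip(pairs, pairs_other)
    ):
        raise ValueError("pairs_other must cover the same subjects in the same order")
    obs2, pred2 = labels(pairs_other)
    reps2 = rep_counts(obs2, pred2)
    diff = reps - reps2
    rows = []
    for k, r in enumerate(RANGES):
        for c, cell in enumerate(("tp", "fp")):
            lo, hi = np.percentile(diff[:, k, c], [2.5, 97.5])
            rows.append(
                {
                    "range": r,
                    "cell": cell,
                    "difference": float(diff[:, k, c].mean()),
                    "ci95_low": float(lo),
                    "ci95_high": float(hi),
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    return table, pd.DataFrame(rows)
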