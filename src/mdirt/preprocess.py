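"""Cohort and condition filters applied to a DiagnosisMatrix before modelling.

Three cohort rules mirror the study design this package supports: drop
patients whose indicator record is almost entirely unknown, drop patients
with none of the modelled conditions, and (optionally) analyse a random
subsample of the eligible pool.  A fourth rule drops condition columns whose
prevalence is too skewed (< 5% or > 95% by default) to carry information for
scaling.  Every filter returns the filtered matrix together with a
:class:`FilterReport`, and the concatenated reports form an auditable
manifest of each n_before → n_after transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .cohort_io import DiagnosisMatrix

logger = logging.getLogger("mdirt")

__all__ = [
    "FilterReport",
    "filter_missing_patients",
    "filter_zero_condition_patients",
    "filter_conditions_by_prevalence",
    "sample_patients",
]


@dataclass
class FilterReport:
    """Audit record of one filtering stage.

    ``n_before``/``n_after`` count units on the filtered axis (patients for
    cohort filters, conditions for the prevalence filter) and always satisfy
    ``n_after == n_before - len(removed)``.
    """

    stage: str
    n_before: int
    n_after: int
    removed: list[str] = field(default_factory=list)
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - len(self.removed):
            raise ValueError("inconsistent filter report counts")

    def to_dict(self) -> dict[str, Any]:
        return {
            "stage": self.stage,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "removed": list(self.removed),
            "parameters": dict(self.parameters),
        }


def filter_missing_patients(
    matrix: DiagnosisMatrix, max_missing_fraction: float = 0.90
) -> tuple[DiagnosisMatrix, FilterReport]:
    """Remove patients whose fraction of missing cells is >= the threshold.

    With 145 conditions and the default 0.90 this removes exactly the
    patients missing at least 131 indicators.
    """
    if not (0 < max_missing_fraction <= 1):
        raise ValueError("max_missing_fraction must be in (0, 1]")
    frac_missing = np.isnan(matrix.values).mean(axis=1) if matrix.n_conditions else np.zeros(0)
    drop = frac_missing >= max_missing_fraction
    removed = [pid for pid, d in zip(matrix.patient_ids, drop) if d]
    kept = [pid for pid, d in zip(matrix.patient_ids, drop) if not d]
    report = FilterReport(
        stage="missing_patients",
        n_before=matrix.n_patients,
        n_after=len(kept),
        removed=removed,
        parameters={"max_missing_fraction": max_missing_fraction},
    )
    if not kept:
        report.parameters["empty_result"] = True
        logger.warning("filter_missing_patients removed every patient")
    return matrix.select_patients(kept), report


def filter_zero_condition_patients(
    matrix: DiagnosisMatrix,
) -> tuple[DiagnosisMatrix, FilterReport]:
    """Remove patients with no observed positive indicator.

    Rows whose observed cells are all 0 — and rows with only missing cells,
    which carry no modelling information — are dropped.
    """
    if matrix.n_patients == 0:
        raise ValueError("matrix has no patients")
    any_positive = np.nansum(matrix.values, axis=1) > 0
    removed = [pid for pid, ok in zip(matrix.patient_ids, any_positive) if not ok]
    kept = [pid for pid, ok in zip(matrix.patient_ids, any_positive) if ok]
    report = FilterReport(
        stage="zero_condition_patients",
        n_before=matrix.n_patients,
        n_after=len(kept),
        removed=removed,
    )
    return matrix.select_patients(kept), report


def filter_conditions_by_prevalence(
    matrix: DiagnosisMatrix, min_prev: float = 0.05, max_prev: float = 0.95
) -> tuple[DiagnosisMatrix, FilterReport]:
    """Drop condition columns with prevalence < min_prev or > max_prev.

    Prevalence is computed over observed (non-missing) cells.  The bounds
    are strict, so a condition at exactly 5% or 95% is retained.  Columns
    dropped for *high* prevalence are listed separately in the report
    parameters — they remain useful descriptively even though they cannot
    support scaling.
    """
    if not (0 <= min_prev < max_prev <= 1):
        raise ValueError("need 0 <= min_prev < max_prev <= 1")
    prev = matrix.prevalence()
    low = [c for c in matrix.condition_names if prev[c] < min_prev or np.isnan(prev[c])]
    high = [c for c in matrix.condition_names if prev[c] > max_prev]
    removed = [c for c in matrix.condition_names if c in set(low) | set(high)]
    kept = [c for c in matrix.condition_names if c not in set(removed)]
    if not kept:
        raise ValueError("prevalence filter dropped every condition; nothing to model")
    report = FilterReport(
        stage="condition_prevalence",
        n_before=matrix.n_conditions,
        n_after=len(kept),
        removed=removed,
        parameters={
            "min_prev": min_prev,
            "max_prev": max_prev,
            "dropped_low": low,
            "dropped_high": high,
        },
    )
    return matrix.select_conditions(kept), report


def sample_patients(
    matrix: DiagnosisMatrix, fraction: float, seed: int
) -> tuple[DiagnosisMatrix, FilterReport]:
    """Simple random sample of patients without replacement.

    The sample size is ``round(fraction * n)``; original row order is
    preserved among sampled patients and the draw is reproducible given
    ``seed``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = matrix.n_patients
    size = int(round(fraction * n))
    if fraction == 1.0:
        report = FilterReport(
            stage="random_sample",
            n_before=n,
            n_after=n,
            parameters={"fraction": fraction, "seed": seed, "no_removal": True},
        )
        return matrix.copy(), report
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=size, replace=False))
    kept = [matrix.patient_ids[i] for i in chosen]
    removed = [pid for pid in matrix.patient_ids if pid not in set(kept)]
    report = FilterReport(
        stage="random_sample",
        n_before=n,
        n_after=size,
        removed=removed,
        parameters={"fraction": fraction, "seed": seed},
    )
    return matrix.select_patients(kept), report
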