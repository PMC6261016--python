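"""Within-subgroup scaling diagnostics: Loevinger's H, monotonicity
checks, scale item selection, and Guttman-error person fit.

Monotone-homogeneity scaling treats the conditions in a subgroup as steps
on a cumulative severity ladder, ordered from most to least prevalent.  A
Guttman error is lacking a common ("easy") condition while having a rarer
("hard") one.  Loevinger's H compares the observed frequency of such error
cells with the frequency expected under marginal independence:

    H_ij = 1 - F_ij / E_ij,   F_ij = #(x_i = 0 and x_j = 1),
                              E_ij = n * P(x_i = 0) * P(x_j = 1),

for item i more prevalent than item j, aggregated over partners for item
coefficients and over all pairs for the scale coefficient.  H = 1 means no
Guttman errors; H around 0 means the items co-occur no more consistently
than independent coins.  A scale coefficient >= 0.3 is conventionally the
minimum for a usable scale.

Monotonicity is checked with restscore groups: the probability of a
condition should not significantly decrease as the count of the *other*
conditions grows.  Person fit counts each patient's Guttman errors under
the prevalence ordering; patients with more than ``max_errors`` (default 1)
are excluded as ill-fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort_io import DiagnosisMatrix
from .preprocess import FilterReport

logger = logging.getLogger("mdirt")

__all__ = [
    "ScaleResult",
    "PersonFit",
    "MonotonicityResult",
    "ScalingError",
    "prevalence_order",
    "pairwise_H",
    "scale_H",
    "check_monotonicity",
    "select_scale_items",
    "guttman_errors",
    "person_fit_filter",
]


class ScalingError(ValueError):
    """A subgroup cannot support a scale (fewer than two usable items)."""


@dataclass
class MonotonicityResult:
    item: str
    verdict: str  # "ok" | "violation" | "indeterminate"
    n_violations: int = 0
    group_sizes: list[int] = field(default_factory=list)
    group_props: list[float] = field(default_factory=list)


@dataclass
class ScaleResult:
    """Loevinger coefficients, monotonicity verdicts, and selected items."""

    item_order: list[str]
    H_pair: pd.DataFrame
    H_item: pd.Series
    H_scale: float
    monotonicity: dict[str, MonotonicityResult] = field(default_factory=dict)
    selected_items: list[str] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)

    @property
    def acceptable(self) -> bool:
        return bool(self.H_scale >= 0.3)


@dataclass
class PersonFit:
    patient_id: str
    guttman_errors: int
    included: bool


def prevalence_order(matrix: DiagnosisMatrix) -> list[str]:
    """Items sorted by descending observed prevalence, ties alphabetical."""
    prev = matrix.prevalence()
    return sorted(matrix.condition_names, key=lambda c: (-prev[c], c))


def _pair_counts(matrix: DiagnosisMatrix, order: list[str]):
    """F and E for every ordered pair (i more prevalent than j), pairwise-complete."""
    V = matrix.data[order].to_numpy()
    I = len(order)
    F = np.full((I, I), np.nan)
    E = np.full((I, I), np.nan)
    for i in range(I):
        for j in range(i + 1, I):
            both = ~np.isnan(V[:, i]) & ~np.isnan(V[:, j])
            n = int(both.sum())
            if n == 0:
                continue
            xi, xj = V[both, i], V[both, j]
            F[i, j] = float(((xi == 0) & (xj == 1)).sum())
            E[i, j] = n * (xi == 0).mean() * (xj == 1).mean()
    return F, E


def pairwise_H(matrix: DiagnosisMatrix) -> pd.DataFrame:
    """Item-by-item Loevinger coefficients (symmetric; NaN where the
    expected error count degenerates to zero)."""
    if matrix.n_conditions < 2 or matrix.n_patients < 2:
        raise ValueError("need at least 2 items and 2 patients")
    order = prevalence_order(matrix)
    F, E = _pair_counts(matrix, order)
    I = len(order)
    H = np.full((I, I), np.nan)
    n_degenerate = 0
    for i in range(I):
        for j in range(i + 1, I):
            if np.isnan(E[i, j]) or E[i, j] == 0:
                n_degenerate += 1
                continue
            H[i, j] = H[j, i] = 1.0 - F[i, j] / E[i, j]
    if n_degenerate:
        logger.warning("pairwise_H: %d degenerate pairs excluded", n_degenerate)
    out = pd.DataFrame(H, index=order, columns=order)
    return out.loc[matrix.condition_names, matrix.condition_names]


def scale_H(matrix: DiagnosisMatrix) -> ScaleResult:
    """Item and scale Loevinger coefficients: H = 1 - sum(F)/sum(E)."""
    if matrix.n_conditions < 2 or matrix.n_patients < 2:
        raise ValueError("need at least 2 items and 2 patients")
    order = prevalence_order(matrix)
    F, E = _pair_counts(matrix, order)
    valid = ~np.isnan(E) & (E > 0)
    H_item = {}
    for idx, item in enumerate(order):
        mask = np.zeros_like(valid)
        mask[idx, :] = valid[idx, :]
        mask[:, idx] = valid[:, idx]
        e_sum = E[mask].sum()
        H_item[item] = 1.0 - F[mask].sum() / e_sum if e_sum > 0 else np.nan
    total_E = E[valid].sum()
    H_scale = 1.0 - F[valid].sum() / total_E if total_E > 0 else np.nan
    Hp = pairwise_H(matrix)
    return ScaleResult(
        item_order=order,
        H_pair=Hp,
        H_item=pd.Series(H_item).loc[matrix.condition_names],
        H_scale=float(H_scale),
        selected_items=list(matrix.condition_names),
    )


def check_monotonicity(
    matrix: DiagnosisMatrix,
    item: str,
    *,
    min_group_size: int = 50,
    n_groups: int | None = None,
    alpha: float = 0.05,
) -> MonotonicityResult:
    """Restscore check of the monotonicity assumption for one item.

    Patients are grouped by their count of positive responses on the other
    items; adjacent groups are merged until each holds at least
    ``min_group_size`` patients.  Any significant *decrease* of the item
    proportion between a lower and a higher restscore group (one-sided
    pooled two-proportion z-test at ``alpha``) is a violation.
    """
    if item not in matrix.condition_names:
        raise ValueError(f"unknown item {item!r}")
    others = [c for c in matrix.condition_names if c != item]
    x = matrix.data[item].to_numpy()
    rest = np.nansum(matrix.data[others].to_numpy(), axis=1)
    obs = ~np.isnan(x)
    x, rest = x[obs], rest[obs]

    levels = np.unique(rest)
    groups = [(lv, x[rest == lv]) for lv in levels]
    if n_groups is not None and len(groups) > n_groups:
        # merge adjacent restscore levels into at most n_groups equal spans
        edges = np.array_split(np.arange(len(groups)), n_groups)
        groups = [
            (groups[idx[0]][0], np.concatenate([groups[i][1] for i in idx]))
            for idx in edges
            if len(idx)
        ]
    # merge small groups forward (and the trailing remainder backward)
    merged: list[np.ndarray] = []
    buf = np.array([])
    for _, vals in groups:
        buf = np.concatenate([buf, vals])
        if len(buf) >= min_group_size:
            merged.append(buf)
            buf = np.array([])
    if len(buf):
        if merged:
            merged[-1] = np.concatenate([merged[-1], buf])
        else:
            merged.append(buf)
    if len(merged) < 2:
        return MonotonicityResult(item=item, verdict="indeterminate")

    sizes = [len(g) for g in merged]
    props = [float(g.mean()) for g in merged]
    z_crit = norm.ppf(1 - alpha)
    n_viol = 0
    for g1 in range(len(merged)):
        for g2 in range(g1 + 1, len(merged)):
            n1, n2 = sizes[g1], sizes[g2]
            p1, p2 = props[g1], props[g2]
            if p1 <= p2:
                continue
            pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            if se == 0:
                continue
            if (p1 - p2) / se > z_crit:
                n_viol += 1
    verdict = "violation" if n_viol else "ok"
    return MonotonicityResult(
        item=item, verdict=verdict, n_violations=n_viol, group_sizes=sizes, group_props=props
    )


def select_scale_items(
    matrix: DiagnosisMatrix,
    *,
    H_min: float = 0.3,
    min_group_size: int = 50,
    alpha: float = 0.05,
    n_groups: int | None = None,
) -> ScaleResult:
    """Iteratively prune items until the survivors form a Mokken scale.

    Phase 1 removes monotonicity violators one at a time (worst first:
    most significant decreases, ties to the lower item coefficient).
    Phase 2 removes items with H_item below ``H_min``, lowest first,
    recomputing coefficients after each removal.  Raises
    :class:`ScalingError` if fewer than two items survive — such a
    subgroup should be described, not scaled.
    """
    current = matrix.copy()
    audit: list[dict] = []

    def _fail(reason: str):
        raise ScalingError(
            f"fewer than 2 scalable items remain ({reason}); "
            "treat this subgroup descriptively"
        )

    if current.n_conditions < 2:
        _fail("fewer than 2 items supplied")

    while True:  # phase 1: monotonicity
        verdicts = {
            c: check_monotonicity(
                current, c, min_group_size=min_group_size, alpha=alpha, n_groups=n_groups
            )
            for c in current.condition_names
        }
        violators = [c for c, v in verdicts.items() if v.verdict == "violation"]
        if not violators:
            break
        H_items = scale_H(current).H_item
        worst = max(
            violators, key=lambda c: (verdicts[c].n_violations, -np.nan_to_num(H_items[c], nan=1.0))
        )
        audit.append(
            {
                "action": "remove",
                "item": worst,
                "reason": "monotonicity violation",
                "n_violations": verdicts[worst].n_violations,
            }
        )
        if current.n_conditions <= 2:
            _fail("monotonicity violations")
        current = current.select_conditions(
            [c for c in current.condition_names if c != worst]
        )

    while True:  # phase 2: Loevinger coefficients
        result = scale_H(current)
        low = result.H_item[result.H_item < H_min]
        if low.empty:
            break
        worst = low.idxmin()
        audit.append(
            {
                "action": "remove",
                "item": worst,
                "reason": f"H_item {low.min():.3f} < {H_min}",
            }
        )
        if current.n_conditions <= 2:
            _fail("low Loevinger coefficients")
        current = current.select_conditions(
            [c for c in current.condition_names if c != worst]
        )

    final = scale_H(current)
    final.monotonicity = {
        c: check_monotonicity(
            current, c, min_group_size=min_group_size, alpha=alpha, n_groups=n_groups
        )
        for c in current.condition_names
    }
    final.selected_items = list(current.condition_names)
    final.audit = audit
    return final


def guttman_errors(pattern: Sequence[float], item_order: Sequence[str] | None = None) -> int:
    """Count Guttman errors in one response pattern.

    ``pattern`` must already be aligned to the prevalence-descending item
    order; an error is any ordered pair (easier item absent, harder item
    present).  Missing entries are skipped pairwise, so appending items the
    person is missing never changes the count.
    """
    v = np.asarray(pattern, dtype=float)
    obs = ~np.isnan(v)
    zeros_before = np.cumsum(np.where(obs, v == 0, 0))
    zeros_before = np.concatenate([[0], zeros_before[:-1]])
    return int(np.sum(zeros_before[obs & (v == 1)]))


def person_fit_filter(
    matrix: DiagnosisMatrix,
    item_order: Sequence[str] | None = None,
    max_errors: int = 1,
) -> tuple[DiagnosisMatrix, list[PersonFit], FilterReport]:
    """Retain patients with at most ``max_errors`` Guttman errors.

    ``item_order`` defaults to descending prevalence within the supplied
    matrix (ties alphabetical).  Returns the filtered matrix, per-person
    error counts, and a filter report carrying the retained fraction.
    """
    if max_errors < 0:
        raise ValueError("max_errors must be >= 0")
    order = list(item_order) if item_order is not None else prevalence_order(matrix)
    V = matrix.data[order].to_numpy()
    fits = []
    for pid, row in zip(matrix.patient_ids, V):
        errs = guttman_errors(row)
        fits.append(PersonFit(patient_id=pid, guttman_errors=errs, included=errs <= max_errors))
    kept = [f.patient_id for f in fits if f.included]
    removed = [f.patient_id for f in fits if not f.included]
    report = FilterReport(
        stage="person_fit",
        n_before=matrix.n_patients,
        n_after=len(kept),
        removed=removed,
        parameters={
            "max_errors": max_errors,
            "item_order": order,
            "retained_fraction": len(kept) / matrix.n_patients if matrix.n_patients else np.nan,
        },
    )
    logger.info(
        "person_fit_filter: retained %d of %d patients (%.1f%%)",
        len(kept),
        matrix.n_patients,
        100.0 * len(kept) / max(matrix.n_patients, 1),
    )
    return matrix.select_patients(kept), fits, report
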