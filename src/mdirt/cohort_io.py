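"""Ingest encounter records and condition dictionaries; build and round-trip
binary diagnosis-indicator matrices.

The modelling stages downstream all operate on a :class:`DiagnosisMatrix` —
patients × conditions with cells in {0, 1, missing}.  Indicators are built
from raw ICD-9 encounter rows by matching each code against a dictionary of
per-condition code patterns (exact codes or prefix wildcards such as
``"303.*"``).  Matching is on the normalized code (decimal point stripped),
so ``"303.*"`` covers ``303``, ``303.9`` and ``303.90`` — the usual way
comorbidity scales define code families.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mdirt")

__all__ = [
    "FormatError",
    "EmptyInputError",
    "ParseReport",
    "EncounterTable",
    "ConditionDefinition",
    "DiagnosisMatrix",
    "load_encounters",
    "load_condition_dictionary",
    "example_condition_dictionary",
    "save_condition_dictionary",
    "build_indicator_matrix",
    "read_matrix",
    "write_matrix",
    "normalize_icd9",
]

#: Lexical form of an ICD-9-CM code: 3 digits, or V/E prefix, optional decimals.
ICD9_RE = re.compile(r"^(?:\d{3}(?:\.\d{1,2})?|V\d{2}(?:\.\d{1,2})?|E\d{3}(?:\.\d)?)$")

VALID_SETTINGS = frozenset({"inpatient", "outpatient", "community"})


class FormatError(ValueError):
    """A file violates the expected tabular format."""


class EmptyInputError(ValueError):
    """An input file contains no usable records."""


def normalize_icd9(code: str) -> str:
    """Uppercase an ICD-9 code and strip the decimal point for comparison."""
    return str(code).strip().upper().replace(".", "")


@dataclass
class ParseReport:
    """Per-file account of rejected rows (line number, offending value, reason)."""

    n_total: int = 0
    n_kept: int = 0
    rejected: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class EncounterTable:
    """Long-format diagnosis encounters.

    ``records`` has columns ``patient_id``, ``icd9`` and optionally
    ``setting`` (inpatient/outpatient/community) and ``date``.
    """

    records: pd.DataFrame
    parse_report: ParseReport | None = None

    def __post_init__(self) -> None:
        required = {"patient_id", "icd9"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"encounter table missing columns: {sorted(missing)}")
        ids = self.records["patient_id"].astype(str)
        if (ids.str.len() == 0).any():
            raise FormatError("encounter table contains empty patient_id")
        bad = [c for c in self.records["icd9"] if not ICD9_RE.match(str(c))]
        if bad:
            raise FormatError(f"malformed ICD-9 codes in encounter table: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in order of first appearance."""
        return list(dict.fromkeys(self.records["patient_id"].astype(str)))


def load_encounters(
    path: str | Path,
    *,
    delimiter: str = ",",
) -> EncounterTable:
    """Read encounter rows from CSV, keeping parseable rows and reporting the rest.

    The file must have columns ``patient_id`` and ``icd9``; ``setting`` and
    ``date`` are optional.  Rows whose ICD-9 code does not match the ICD-9
    lexical form are rejected and listed in the parse report with their line
    numbers; all other rows are kept in file order.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    for col in ("patient_id", "icd9"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no encounter rows (header only)")

    report = ParseReport(n_total=len(raw))
    keep = np.ones(len(raw), dtype=bool)
    for pos, (pid, code) in enumerate(zip(raw["patient_id"], raw["icd9"])):
        line_no = pos + 2  # 1-based, after header
        if not str(pid).strip():
            keep[pos] = False
            report.rejected.append((line_no, str(pid), "empty patient_id"))
        elif not ICD9_RE.match(str(code).strip().upper()):
            keep[pos] = False
            report.rejected.append((line_no, str(code), "malformed ICD-9 code"))
    kept = raw.loc[keep].copy()
    kept["patient_id"] = kept["patient_id"].astype(str).str.strip()
    kept["icd9"] = kept["icd9"].astype(str).str.strip().str.upper()
    if "date" in kept.columns:
        kept["date"] = pd.to_datetime(kept["date"], errors="coerce")
    report.n_kept = len(kept)
    if report.rejected:
        logger.warning(
            "load_encounters: rejected %d of %d rows", report.n_rejected, report.n_total
        )
    if len(kept) == 0:
        raise EmptyInputError(f"{path}: no parseable encounter rows")
    return EncounterTable(records=kept.reset_index(drop=True), parse_report=report)


# ---------------------------------------------------------------------------
# Condition dictionaries
# ---------------------------------------------------------------------------

_PATTERN_RE = re.compile(r"^(?:\d{1,3}|V\d{0,2}|E\d{0,3})(?:\.[\d*]{0,2})?\*?$")


def _compile_pattern(pattern: str) -> tuple[str, str]:
    """Return ("prefix"|"exact", normalized stem) for an ICD-9 pattern."""
    p = str(pattern).strip().upper()
    if p.endswith("*"):
        stem = normalize_icd9(p[:-1].rstrip("."))
        if not stem or not re.match(r"^[VE]?\d+$", stem):
            raise ValueError(f"invalid ICD-9 pattern: {pattern!r}")
        return "prefix", stem
    if not ICD9_RE.match(p):
        raise ValueError(f"invalid ICD-9 pattern: {pattern!r}")
    return "exact", normalize_icd9(p)


@dataclass
class ConditionDefinition:
    """One named condition defined by a list of ICD-9 code patterns."""

    name: str
    code_patterns: list[str]
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("condition name must be non-empty")
        if not self.code_patterns:
            raise ValueError(f"condition {self.name!r} has no code patterns")
        self._compiled = [_compile_pattern(p) for p in self.code_patterns]

    def matches(self, code: str) -> bool:
        norm = normalize_icd9(code)
        for kind, stem in self._compiled:
            if kind == "exact":
                if norm == stem:
                    return True
            elif norm.startswith(stem):
                return True
        return False


def load_condition_dictionary(path: str | Path) -> list[ConditionDefinition]:
    """Load a YAML/JSON document of ``[{name, code_patterns, notes?}, ...]``."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, list) or not data:
        raise FormatError(f"{path}: expected a non-empty list of condition entries")
    defs = [
        ConditionDefinition(
            name=entry["name"],
            code_patterns=list(entry["code_patterns"]),
            notes=entry.get("notes", ""),
        )
        for entry in data
    ]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate condition names")
    return defs


def example_condition_dictionary() -> list[ConditionDefinition]:
    """The synthetic example dictionary shipped with the package."""
    return load_condition_dictionary(
        Path(__file__).parent / "data" / "example_conditions.yaml"
    )


def save_condition_dictionary(
    dictionary: Sequence[ConditionDefinition], path: str | Path
) -> None:
    path = Path(path)
    data = [
        {"name": d.name, "code_patterns": list(d.code_patterns), "notes": d.notes}
        for d in dictionary
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# DiagnosisMatrix
# ---------------------------------------------------------------------------


@dataclass
class DiagnosisMatrix:
    """Patients × conditions binary indicators with a missingness mask.

    Stored as a float DataFrame: 1.0 = has condition, 0.0 = does not,
    NaN = unknown.  Row index holds patient ids; columns hold condition
    names.  Observed cells must be strictly binary and ids/names unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        if df.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate condition names")
        vals = df.to_numpy()
        observed = ~np.isnan(vals)
        if not np.isin(vals[observed], (0.0, 1.0)).all():
            raise ValueError("observed cells must be 0 or 1")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self.data = df

    # -- basic views --------------------------------------------------------
    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Float array with NaN marking missing cells."""
        return self.data.to_numpy()

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def prevalence(self) -> pd.Series:
        """Per-condition prevalence over observed (non-missing) cells."""
        return self.data.mean(axis=0, skipna=True)

    # -- subsetting ---------------------------------------------------------
    def select_patients(self, ids: Iterable[str]) -> "DiagnosisMatrix":
        return DiagnosisMatrix(self.data.loc[list(ids)].copy())

    def select_conditions(self, names: Iterable[str]) -> "DiagnosisMatrix":
        return DiagnosisMatrix(self.data.loc[:, list(names)].copy())

    def copy(self) -> "DiagnosisMatrix":
        return DiagnosisMatrix(self.data.copy())

    def equals(self, other: "DiagnosisMatrix") -> bool:
        if self.patient_ids != other.patient_ids:
            return False
        if self.condition_names != other.condition_names:
            return False
        a, b = self.values, other.values
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())


def build_indicator_matrix(
    encounters: EncounterTable,
    dictionary: Sequence[ConditionDefinition],
    min_occurrences: int = 1,
    *,
    settings: Iterable[str] | None = None,
    window: tuple | None = None,
) -> DiagnosisMatrix:
    """Binary indicators from encounters: cell (p, c) = 1 iff patient p has at
    least ``min_occurrences`` encounters matching any pattern of condition c.

    All patients present in ``encounters`` get a row, even if no code matches
    (cohort filtering is a later stage).  A code matched by the patterns of
    two different conditions sets both columns and triggers a logged warning.

    Parameters
    ----------
    settings : restrict to these encounter settings (needs a ``setting`` column).
    window : ``(start, end)`` date interval; rows without a parseable date are
        excluded when a window is given (needs a ``date`` column).
    """
    if not dictionary:
        raise ValueError("condition dictionary must be non-empty")
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be a positive integer")
    names = [d.name for d in dictionary]
    if len(set(names)) != len(names):
        raise ValueError("duplicate condition names in dictionary")

    rec = encounters.records
    if settings is not None:
        if "setting" not in rec.columns:
            raise FormatError("settings filter requested but no 'setting' column")
        rec = rec[rec["setting"].isin(set(settings))]
    if window is not None:
        if "date" not in rec.columns:
            raise FormatError("date window requested but no 'date' column")
        start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        dates = pd.to_datetime(rec["date"], errors="coerce")
        rec = rec[(dates >= start) & (dates <= end)]

    patients = encounters.patient_ids  # full roster, pre-filter, keeps all rows
    counts = pd.DataFrame(0, index=patients, columns=names, dtype=int)
    overlap_codes: set[str] = set()
    # cache pattern matches per distinct code
    match_cache: dict[str, list[str]] = {}
    for pid, code in zip(rec["patient_id"].astype(str), rec["icd9"]):
        hit = match_cache.get(code)
        if hit is None:
            hit = [d.name for d in dictionary if d.matches(code)]
            match_cache[code] = hit
        if len(hit) > 1:
            overlap_codes.add(code)
        for name in hit:
            counts.loc[pid, name] += 1
    if overlap_codes:
        logger.warning(
            "build_indicator_matrix: codes matched by multiple conditions: %s",
            sorted(overlap_codes),
        )
    return DiagnosisMatrix((counts >= min_occurrences).astype(float))


# ---------------------------------------------------------------------------
# Matrix round-trip
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, *, na_token: str = "NA") -> DiagnosisMatrix:
    """Read a patients × conditions CSV (first column ``patient_id``)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if raw.columns[0] != "patient_id":
        raise FormatError(f"{path}: first column must be 'patient_id'")
    raw = raw.set_index("patient_id")
    cells = raw.to_numpy(dtype=str)
    cells = np.char.strip(cells)
    valid = {na_token: np.nan, "0": 0.0, "1": 1.0}
    bad = ~np.isin(cells, list(valid))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-binary cell {cells[r, c]!r} at "
            f"(row {r + 2}, col {raw.columns[c]!r})"
        )
    values = np.where(cells == "1", 1.0, np.where(cells == "0", 0.0, np.nan))
    parsed = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    return DiagnosisMatrix(parsed)


def write_matrix(
    matrix: DiagnosisMatrix, path: str | Path, *, na_token: str = "NA"
) -> None:
    """Write a matrix as CSV so that ``read_matrix`` recovers it exactly."""
    out = matrix.data.copy()
    formatted = out.map(lambda v: na_token if np.isnan(v) else str(int(v)))
    formatted.index.name = "patient_id"
    formatted.to_csv(path)
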