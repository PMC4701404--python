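"""Domain types, dataset IO and structural validation.

A *validation study* evaluates an existing clinical prediction rule against a
reference outcome in new patients, yielding a diagnostic 2x2 table
(TP/FP/FN/TN).  Studies belong to a *meta-analysis* (one prediction rule at
one threshold), and each carries a profile of design characteristics
(patient selection, disease spectrum, verification, ...) whose influence on
apparent performance the downstream meta-regression estimates.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger("metaepi")

__all__ = [
    "DESIGN_LEVELS",
    "DESIGN_CHARACTERISTICS",
    "DatasetError",
    "TwoByTwoTable",
    "DesignProfile",
    "ValidationStudy",
    "MetaAnalysisSet",
    "DatasetReport",
    "classify_sample_size",
    "normalize_level",
    "read_studies",
    "write_studies",
    "validate_dataset",
    "MIN_STUDIES_PER_META",
]

#: Enumerated levels of each design characteristic. "unclear" is always legal:
#: unreported characteristics are treated as unclear, never as errors.
DESIGN_LEVELS: Mapping[str, tuple[str, ...]] = {
    "sample_size": ("adequate", "inadequate"),
    "patient_selection": ("consecutive", "nonconsecutive", "unclear"),
    "spectrum": ("cohort", "case_control", "unclear"),
    "validation_type": ("broad", "narrow", "internal", "unclear"),
    "assessment": ("blind", "nonblind", "unclear"),
    "verification": ("complete", "partial", "differential", "unclear"),
    "data_collection": ("prospective", "retrospective", "unclear"),
}

DESIGN_CHARACTERISTICS: tuple[str, ...] = tuple(DESIGN_LEVELS)

COUNT_COLUMNS: tuple[str, ...] = ("tp", "fp", "fn", "tn")
REQUIRED_COLUMNS: tuple[str, ...] = ("meta_id", "study_id") + COUNT_COLUMNS

#: Meta-analyses pooling fewer studies than this are ineligible for fitting.
MIN_STUDIES_PER_META = 4

# Fixed alias table applied after lowercasing and separator normalization.
_ALIASES: Mapping[str, str] = {
    "non_consecutive": "nonconsecutive",
    "casecontrol": "case_control",
    "case_referent": "case_control",
    "reversed_flow": "case_control",
    "blinded": "blind",
    "nonblinded": "nonblind",
    "non_blind": "nonblind",
    "not_reported": "unclear",
    "unreported": "unclear",
    "unknown": "unclear",
    "nr": "unclear",
    "na": "unclear",
    "nan": "unclear",
    "none": "unclear",
    "": "unclear",
}


class DatasetError(ValueError):
    """Schema or row-level problem in an input dataset."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Diagnostic 2x2 table of a validation study.

    ``tp``/``fn`` count outcome-positive patients with positive/negative
    predictions; ``fp``/``tn`` the outcome-negative patients.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in COUNT_COLUMNS:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise DatasetError(f"count {name}={v!r} is not an integer")
            if v < 0:
                raise DatasetError(f"count {name}={v} is negative")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return min(self.tp, self.fp, self.fn, self.tn) == 0

    @property
    def usable(self) -> bool:
        """Both arms populated — required for any accuracy statistic."""
        return self.n_diseased >= 1 and self.n_nondiseased >= 1

    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


def classify_sample_size(table: TwoByTwoTable) -> str:
    """Adequate iff at least 100 patients with AND without the outcome."""
    return (
        "adequate"
        if table.n_diseased >= 100 and table.n_nondiseased >= 100
        else "inadequate"
    )


def normalize_level(characteristic: str, raw: object) -> str:
    """Map a raw cell value onto an enumerated design level.

    Normalization is case-insensitive, treats ``-``, ``/`` and whitespace as
    equivalent separators, and routes a fixed alias table.  Unknown values
    become ``"unclear"`` with a logged warning (unreported design features
    are unclear, not errors).
    """
    if characteristic not in DESIGN_LEVELS:
        raise KeyError(f"unknown design characteristic {characteristic!r}")
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return "unclear"
    s = str(raw).strip().lower()
    for sep in "-/ ":
        s = s.replace(sep, "_")
    s = "_".join(p for p in s.split("_") if p)
    s = _ALIASES.get(s, s)
    if s not in DESIGN_LEVELS[characteristic]:
        log.warning(
            "unknown %s level %r mapped to 'unclear'", characteristic, raw
        )
        return "unclear"
    return s


@dataclass(frozen=True)
class DesignProfile:
    """One level per design characteristic for a validation study."""

    sample_size: str = "inadequate"
    patient_selection: str = "unclear"
    spectrum: str = "unclear"
    validation_type: str = "unclear"
    assessment: str = "unclear"
    verification: str = "unclear"
    data_collection: str = "unclear"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in DESIGN_LEVELS[f.name]:
                raise DatasetError(
                    f"{f.name}={v!r} is not one of {DESIGN_LEVELS[f.name]}"
                )

    def level(self, characteristic: str) -> str:
        return getattr(self, characteristic)

    @classmethod
    def from_raw(
        cls,
        raw: Mapping[str, object],
        table: TwoByTwoTable | None = None,
        context: str = "",
    ) -> "DesignProfile":
        """Build a profile from raw cells, normalizing every level.

        ``sample_size`` may be supplied explicitly or derived from the 2x2
        table counts; when both are available and disagree the explicit value
        wins (manual extraction is authoritative) and a warning is logged.
        """
        values: dict[str, str] = {}
        for char in DESIGN_CHARACTERISTICS:
            if char == "sample_size":
                continue
            values[char] = normalize_level(char, raw.get(char))
        explicit = raw.get("sample_size")
        has_explicit = explicit is not None and not (
            isinstance(explicit, float) and pd.isna(explicit)
        ) and str(explicit).strip() != ""
        if has_explicit:
            lvl = str(explicit).strip().lower()
            if lvl not in DESIGN_LEVELS["sample_size"]:
                raise DatasetError(
                    f"sample_size={explicit!r} must be adequate/inadequate"
                    + (f" ({context})" if context else "")
                )
            if table is not None and classify_sample_size(table) != lvl:
                log.warning(
                    "explicit sample_size %r disagrees with counts (%s)%s;"
                    " keeping the explicit value",
                    lvl,
                    classify_sample_size(table),
                    f" for {context}" if context else "",
                )
            values["sample_size"] = lvl
        elif table is not None:
            values["sample_size"] = classify_sample_size(table)
        else:
            raise DatasetError(
                "sample_size missing and no 2x2 table to derive it from"
                + (f" ({context})" if context else "")
            )
        return cls(**values)


@dataclass(frozen=True)
class ValidationStudy:
    study_id: str
    meta_id: str
    table: TwoByTwoTable
    design: DesignProfile


@dataclass(frozen=True)
class MetaAnalysisSet:
    """Ordered collection of validation studies of one rule at one threshold."""

    meta_id: str
    studies: tuple[ValidationStudy, ...]
    label: str = ""

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def eligible(self) -> bool:
        return self.n_studies >= MIN_STUDIES_PER_META

    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]


def _coerce_count(value: object, column: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise DatasetError(f"row {row}: {column}={value!r} is not a number")
    if not f.is_integer():
        raise DatasetError(f"row {row}: {column}={value!r} is not an integer")
    i = int(f)
    if i < 0:
        raise DatasetError(f"row {row}: {column}={i} is negative")
    return i


def _frame_to_sets(df: pd.DataFrame) -> list[MetaAnalysisSet]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")
    grouped: dict[str, list[ValidationStudy]] = {}
    labels: dict[str, str] = {}
    for pos, (_, row) in enumerate(df.iterrows()):
        rownum = pos + 2  # 1-based with header row
        counts = {c: _coerce_count(row[c], c, rownum) for c in COUNT_COLUMNS}
        table = TwoByTwoTable(**counts)
        meta_id = str(row["meta_id"]).strip()
        study_id = str(row["study_id"]).strip()
        if not meta_id or not study_id:
            raise DatasetError(f"row {rownum}: empty meta_id or study_id")
        design = DesignProfile.from_raw(
            {c: row.get(c) for c in DESIGN_CHARACTERISTICS},
            table=table,
            context=f"row {rownum} ({study_id})",
        )
        grouped.setdefault(meta_id, []).append(
            ValidationStudy(study_id, meta_id, table, design)
        )
        if "label" in df.columns and meta_id not in labels:
            lab = row.get("label")
            labels[meta_id] = "" if pd.isna(lab) else str(lab)
    return [
        MetaAnalysisSet(mid, tuple(studies), labels.get(mid, ""))
        for mid, studies in grouped.items()
    ]


def read_studies(
    path: str | Path,
    fmt: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> list[MetaAnalysisSet]:
    """Read a study-level dataset (CSV or XLSX) grouped by meta-analysis.

    ``column_map`` maps dataset column names onto the canonical schema
    (``{"Meta ID": "meta_id", ...}``); spreadsheet layouts vary, so the
    mapping is user-configurable rather than hard-coded.  Groups preserve
    file order.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"input file not found: {path}")
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    else:
        raise DatasetError(f"unknown format {fmt!r} (expected csv or xlsx)")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return _frame_to_sets(df)


def studies_frame(sets: Iterable[MetaAnalysisSet]) -> pd.DataFrame:
    rows = []
    for ms in sets:
        for st in ms.studies:
            row = {"meta_id": st.meta_id, "study_id": st.study_id}
            row.update(dict(zip(COUNT_COLUMNS, st.table.counts())))
            row.update(asdict(st.design))
            if ms.label:
                row["label"] = ms.label
            rows.append(row)
    return pd.DataFrame(rows)


def write_studies(sets: Iterable[MetaAnalysisSet], path: str | Path) -> None:
    """Write the canonical CSV dialect (round-trips through read_studies)."""
    studies_frame(sets).to_csv(path, index=False)


@dataclass
class DatasetReport:
    """Structural validation summary of a dataset."""

    n_meta: int
    n_studies: int
    per_meta_counts: dict[str, int]
    ineligible: list[str] = field(default_factory=list)
    issues: list[str] = field(default_factory=list)
    level_frequencies: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def validate_dataset(sets: Sequence[MetaAnalysisSet]) -> DatasetReport:
    """Check pipeline eligibility and invariants; never raises on content.

    Flags meta-analyses pooling fewer than four studies (excluded from
    fitting), duplicate study ids within a meta-analysis, and studies with an
    empty arm; tallies level frequencies per design characteristic.
    """
    sets = list(sets)
    if not sets:
        raise DatasetError("empty dataset: no meta-analyses")
    per_meta = {ms.meta_id: ms.n_studies for ms in sets}
    issues: list[str] = []
    ineligible: list[str] = []
    freqs: dict[str, dict[str, int]] = {
        c: {lvl: 0 for lvl in DESIGN_LEVELS[c]} for c in DESIGN_CHARACTERISTICS
    }
    for ms in sets:
        if not ms.eligible:
            ineligible.append(ms.meta_id)
            issues.append(
                f"meta-analysis {ms.meta_id} has {ms.n_studies} studies"
                f" (< {MIN_STUDIES_PER_META}): excluded from fitting"
            )
        seen: set[str] = set()
        for st in ms.studies:
            if st.study_id in seen:
                issues.append(
                    f"duplicate study_id {st.study_id!r} in meta-analysis"
                    f" {ms.meta_id}"
                )
            seen.add(st.study_id)
            if not st.table.usable:
                issues.append(
                    f"study {st.study_id} ({ms.meta_id}) has an empty arm"
                )
            for c in DESIGN_CHARACTERISTICS:
                freqs[c][st.design.level(c)] += 1
    return DatasetReport(
        n_meta=len(sets),
        n_studies=sum(per_meta.values()),
        per_meta_counts=per_meta,
        ineligible=ineligible,
        issues=issues,
        level_frequencies=freqs,
    )
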