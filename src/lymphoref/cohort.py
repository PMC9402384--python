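"""Domain model for pediatric immunophenotyping cohorts.

A cohort is a tidy table of subjects — one row per child with sex, age and
one column per analyte (lymphocyte-subset percentages, absolute counts in
cells/µl, and the CD4/CD8 ratio). This module defines the analyte panel,
the age-group scheme used for partitioning, and validated loading of the
cohort CSV contract that every downstream stage consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: days per mean Gregorian month, used to convert an age in days to
#: completed months deterministically.
DAYS_PER_MONTH = 30.44

#: oldest includable age, in completed months (18 years = 227 completed months).
MAX_AGE_MONTHS = 227


class CohortSchemaError(ValueError):
    """The cohort table is missing required columns or malformed."""


class AgeOutOfRangeError(ValueError):
    """Age falls outside the 0-18 year inclusion window."""


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"


class AnalyteKind(str, Enum):
    PERCENTAGE = "percentage"
    COUNT = "count"
    RATIO = "ratio"


class AgeUnit(str, Enum):
    DAYS = "days"
    MONTHS = "months"
    YEARS = "years"


@dataclass(frozen=True)
class AnalyteDefinition:
    """One analyte of the panel: a percentage of lymphocytes, an absolute
    count (cells/µl) or the CD4/CD8 ratio."""

    name: str
    kind: AnalyteKind
    phenotype_label: str
    units: str

    def valid_value(self, x: float) -> bool:
        if not np.isfinite(x) or x < 0:
            return False
        if self.kind is AnalyteKind.PERCENTAGE and x > 100:
            return False
        return True


#: The built-in single-platform flow-cytometry panel: 7 subset percentages
#: (of total lymphocytes), the CD4/CD8 ratio and 8 absolute counts.
DEFAULT_PANEL: tuple[AnalyteDefinition, ...] = (
    AnalyteDefinition("pct_T", AnalyteKind.PERCENTAGE, "CD3+", "%"),
    AnalyteDefinition("pct_CD4", AnalyteKind.PERCENTAGE, "CD3+CD4+", "%"),
    AnalyteDefinition("pct_CD8", AnalyteKind.PERCENTAGE, "CD3+CD8+", "%"),
    AnalyteDefinition("ratio_CD4_CD8", AnalyteKind.RATIO, "CD4+/CD8+", ""),
    AnalyteDefinition("pct_DNT", AnalyteKind.PERCENTAGE, "CD3+CD4-CD8-", "%"),
    AnalyteDefinition("pct_B", AnalyteKind.PERCENTAGE, "CD3-CD19+", "%"),
    AnalyteDefinition("pct_NK", AnalyteKind.PERCENTAGE, "CD3-CD56+", "%"),
    AnalyteDefinition("pct_NKT", AnalyteKind.PERCENTAGE, "CD3+CD56+", "%"),
    AnalyteDefinition("cnt_lymph", AnalyteKind.COUNT, "lymphocytes", "cells/µl"),
    AnalyteDefinition("cnt_T", AnalyteKind.COUNT, "CD3+", "cells/µl"),
    AnalyteDefinition("cnt_CD4", AnalyteKind.COUNT, "CD3+CD4+", "cells/µl"),
    AnalyteDefinition("cnt_CD8", AnalyteKind.COUNT, "CD3+CD8+", "cells/µl"),
    AnalyteDefinition("cnt_DNT", AnalyteKind.COUNT, "CD3+CD4-CD8-", "cells/µl"),
    AnalyteDefinition("cnt_B", AnalyteKind.COUNT, "CD3-CD19+", "cells/µl"),
    AnalyteDefinition("cnt_NK", AnalyteKind.COUNT, "CD3-CD56+", "cells/µl"),
    AnalyteDefinition("cnt_NKT", AnalyteKind.COUNT, "CD3+CD56+", "cells/µl"),
)

PANEL_BY_NAME: dict[str, AnalyteDefinition] = {a.name: a for a in DEFAULT_PANEL}


@dataclass(frozen=True)
class AgeBin:
    label: str
    min_months: int  # inclusive, completed months
    max_months: int  # inclusive

    def contains(self, months: int) -> bool:
        return self.min_months <= months <= self.max_months


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered, contiguous, non-overlapping age bins covering 0-227 completed
    months."""

    bins: tuple[AgeBin, ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("scheme needs at least one bin")
        prev_end = -1
        for b in self.bins:
            if b.min_months != prev_end + 1:
                raise ValueError(
                    f"bins must be contiguous and ordered; gap before {b.label!r}"
                )
            if b.max_months < b.min_months:
                raise ValueError(f"bin {b.label!r} is empty")
            prev_end = b.max_months
        if self.bins[0].min_months != 0 or self.bins[-1].max_months != MAX_AGE_MONTHS:
            raise ValueError(f"bins must cover [0, {MAX_AGE_MONTHS}] completed months")

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    def locate(self, months: int) -> AgeBin:
        for b in self.bins:
            if b.contains(months):
                return b
        raise AgeOutOfRangeError(
            f"age of {months} completed months is outside [0, {MAX_AGE_MONTHS}]"
        )


#: Developmental-stage scheme: neonatal, infancy, early childhood, preschool,
#: school age.
DEFAULT_AGE_SCHEME = AgeGroupScheme(
    (
        AgeBin("0-1 month", 0, 1),
        AgeBin("2-12 months", 2, 12),
        AgeBin("1-3 years", 13, 47),
        AgeBin("4-6 years", 48, 83),
        AgeBin("7-18 years", 84, 227),
    )
)


def age_to_months(age_value: float, age_unit: str | AgeUnit) -> int:
    """Convert an age to completed months.

    days -> floor(days / 30.44); months -> floor(months); years -> floor(12*years).
    """
    unit = AgeUnit(age_unit)
    if not np.isfinite(age_value) or age_value < 0:
        raise AgeOutOfRangeError(f"age_value must be a finite non-negative number, got {age_value}")
    if unit is AgeUnit.DAYS:
        return math.floor(age_value / DAYS_PER_MONTH)
    if unit is AgeUnit.MONTHS:
        return math.floor(age_value)
    return math.floor(12 * age_value)


def age_to_group(
    age_value: float,
    age_unit: str | AgeUnit,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> str:
    """Return the label of the unique age bin containing this age."""
    months = age_to_months(age_value, age_unit)
    if months > MAX_AGE_MONTHS:
        raise AgeOutOfRangeError(
            f"age of {months} completed months exceeds the 18-year inclusion limit"
        )
    return scheme.locate(months).label


@dataclass
class SubjectRecord:
    """One child: identifier, sex, age and the analyte measurements."""

    subject_id: str
    sex: Sex
    age_value: float
    age_unit: AgeUnit
    measurements: dict[str, float] = field(default_factory=dict)

    @property
    def age_months(self) -> int:
        return age_to_months(self.age_value, self.age_unit)


@dataclass
class RowDiagnostic:
    """Why a row of the input table was rejected."""

    row: int
    column: str
    message: str


@dataclass
class AnalyteSeries:
    """Per-analyte, per-group vector flowing through the pipeline, with a
    provenance flag per value (raw | transformed | outlier-removed)."""

    analyte: AnalyteDefinition
    group_label: str
    values: np.ndarray
    provenance: np.ndarray  # array of strings, same length

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AnalyteSeries values must be finite")


@dataclass
class CohortLoadResult:
    records: list[SubjectRecord]
    rejected: list[RowDiagnostic]
    frame: pd.DataFrame  # validated rows only, with age_months/age_group added

    def __len__(self) -> int:
        return len(self.records)


REQUIRED_COLUMNS = ("subject_id", "sex", "age_value", "age_unit")


def load_cohort(
    source: str | Path | pd.DataFrame,
    panel: Sequence[AnalyteDefinition] = DEFAULT_PANEL,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> CohortLoadResult:
    """Load and validate a cohort table (CSV path or DataFrame).

    Rows violating an invariant (bad sex code, age out of range, analyte out
    of its admissible range, duplicate id) are rejected with row-level
    diagnostics, never silently dropped. The CD4/CD8 ratio is derived from
    cnt_CD4 / cnt_CD8 when its column is absent.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source)
    else:
        df = source.copy()

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table is missing required columns: {missing}")

    panel_names = [a.name for a in panel]
    analyte_cols = [c for c in df.columns if c in panel_names]
    derive_ratio = (
        "ratio_CD4_CD8" in panel_names
        and "ratio_CD4_CD8" not in df.columns
        and {"cnt_CD4", "cnt_CD8"} <= set(df.columns)
    )
    if not analyte_cols and not derive_ratio:
        raise CohortSchemaError("cohort table has no recognized analyte columns")

    if df.empty:
        logger.warning("cohort table is empty")
        frame = df.assign(age_months=pd.Series(dtype=int), age_group=pd.Series(dtype=str))
        return CohortLoadResult([], [], frame)

    records: list[SubjectRecord] = []
    rejected: list[RowDiagnostic] = []
    keep_idx: list[int] = []
    months_col: list[int] = []
    group_col: list[str] = []
    seen_ids: set[str] = set()
    by_name = {a.name: a for a in panel}

    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        sid = str(rowd["subject_id"])
        if sid in seen_ids:
            rejected.append(RowDiagnostic(i, "subject_id", f"duplicate subject_id {sid!r}"))
            continue
        try:
            sex = Sex(str(rowd["sex"]).strip().upper())
        except ValueError:
            rejected.append(RowDiagnostic(i, "sex", f"invalid sex code {rowd['sex']!r} (expect M/F)"))
            continue
        try:
            unit = AgeUnit(str(rowd["age_unit"]).strip().lower())
            age_val = float(rowd["age_value"])
            months = age_to_months(age_val, unit)
            if months > MAX_AGE_MONTHS:
                raise AgeOutOfRangeError(f"{months} completed months > {MAX_AGE_MONTHS}")
            group = scheme.locate(months).label
        except (ValueError, AgeOutOfRangeError) as e:
            rejected.append(RowDiagnostic(i, "age_value", str(e)))
            continue

        meas: dict[str, float] = {}
        bad = False
        for col in analyte_cols:
            raw = rowd[col]
            if pd.isna(raw):
                continue
            try:
                x = float(raw)
            except (TypeError, ValueError):
                rejected.append(RowDiagnostic(i, col, f"non-numeric value {raw!r}"))
                bad = True
                break
            if not by_name[col].valid_value(x):
                kind = by_name[col].kind.value
                rejected.append(
                    RowDiagnostic(i, col, f"value {x} outside admissible range for {kind} analyte")
                )
                bad = True
                break
            meas[col] = x
        if bad:
            continue

        if derive_ratio and "cnt_CD4" in meas and "cnt_CD8" in meas and meas["cnt_CD8"] > 0:
            meas["ratio_CD4_CD8"] = meas["cnt_CD4"] / meas["cnt_CD8"]

        seen_ids.add(sid)
        records.append(SubjectRecord(sid, sex, age_val, unit, meas))
        keep_idx.append(i)
        months_col.append(months)
        group_col.append(group)

    frame = df.iloc[keep_idx].reset_index(drop=True)
    frame["subject_id"] = frame["subject_id"].astype(str)
    frame["sex"] = frame["sex"].astype(str).str.strip().str.upper()
    if derive_ratio:
        ratio = [r.measurements.get("ratio_CD4_CD8", np.nan) for r in records]
        frame["ratio_CD4_CD8"] = ratio
    frame["age_months"] = months_col
    frame["age_group"] = group_col
    for d in rejected:
        logger.warning("rejected row %d (%s): %s", d.row, d.column, d.message)
    return CohortLoadResult(records, rejected, frame)


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort frame back to the CSV contract (helper columns dropped)."""
    out = frame.drop(columns=[c for c in ("age_months", "age_group") if c in frame.columns])
    out.to_csv(path, index=False)


def panel_analytes(frame: pd.DataFrame, panel: Sequence[AnalyteDefinition] = DEFAULT_PANEL) -> list[AnalyteDefinition]:
    """Panel analytes actually present as columns, in panel order."""
    return [a for a in panel if a.name in frame.columns]
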