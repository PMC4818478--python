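"""CSV schemas for assessments, rating matrices, judgments, and cohorts.

All readers validate eagerly and report offending rows by line number
(1-based, counting the header as line 1).  Writers produce files the readers
round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import RatingMatrix
from .core import ClassificationError, TriageAssessment

ASSESSMENT_COLUMNS = ["id", "request_type", "comorbidity", "functionality", "prognosis"]
JUDGMENT_COLUMNS = ["vignette_id", "rater_id", "likert", "last_bed"]
COHORT_COLUMNS = ["patient_id", "priority", "admitted", "died", "palliative"]


class SchemaError(ValueError):
    """A CSV file does not match its expected schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_assessments(path: str | Path) -> tuple[list[object], list[TriageAssessment]]:
    """Read a triage questionnaire CSV; returns (ids, assessments).

    Answers may be integer codes or mnemonic strings (case-insensitive).
    """
    df = pd.read_csv(path)
    _require_columns(df, ASSESSMENT_COLUMNS, path)
    ids, assessments = [], []
    for i, row in df.iterrows():
        line = i + 2
        try:
            assessments.append(
                TriageAssessment(
                    row["request_type"],
                    row["comorbidity"],
                    row["functionality"],
                    row["prognosis"],
                )
            )
        except ClassificationError as exc:
            raise SchemaError(f"{path}: line {line}: {exc}") from exc
        ids.append(row["id"])
    return ids, assessments


def write_assessments(
    path: str | Path,
    ids: list[object],
    assessments: list[TriageAssessment],
    priorities: list[object] | None = None,
) -> None:
    rows = []
    for i, ident in enumerate(ids):
        a = assessments[i]
        row = {
            "id": ident,
            "request_type": a.request_type.name,
            "comorbidity": a.comorbidity.name,
            "functionality": a.functionality.name,
            "prognosis": a.prognosis.name,
        }
        if priorities is not None:
            row["priority"] = int(priorities[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rating_matrix(path: str | Path, category_count: int = 4) -> RatingMatrix:
    """Read a ratings CSV: `vignette_id`, optional `reference`, one column per rater."""
    df = pd.read_csv(path)
    _require_columns(df, ["vignette_id"], path)
    df = df.set_index("vignette_id")
    reference = None
    if "reference" in df.columns:
        reference = df.pop("reference")
    if df.shape[1] < 1:
        raise SchemaError(f"{path}: no rater columns found")
    values = df.to_numpy(dtype=float)
    bad = np.isfinite(values) & (
        (values < 1) | (values > category_count) | (values != np.round(values))
    )
    if bad.any():
        lines = sorted({int(i) + 2 for i in np.where(bad.any(axis=1))[0]})
        raise SchemaError(
            f"{path}: ratings outside 1..{category_count} at line(s) {lines}"
        )
    return RatingMatrix(df, reference=reference, category_count=category_count)


def write_rating_matrix(path: str | Path, m: RatingMatrix) -> None:
    out = m.ratings.copy()
    if m.reference is not None:
        out.insert(0, "reference", m.reference)
    out.index.name = "vignette_id"
    # keep integer appearance while allowing missing cells
    out.to_csv(path, float_format="%.0f")


def read_judgments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, JUDGMENT_COLUMNS, path)
    bad = ~df["likert"].isin([1, 2, 3, 4])
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]
        raise SchemaError(f"{path}: likert outside 1..4 at line(s) {lines}")
    if not df["last_bed"].isin([0, 1, True, False]).all():
        bad = ~df["last_bed"].isin([0, 1, True, False])
        lines = [int(i) + 2 for i in df.index[bad]]
        raise SchemaError(f"{path}: last_bed must be 0/1 at line(s) {lines}")
    df["last_bed"] = df["last_bed"].astype(bool)
    return df


def write_judgments(path: str | Path, judgments: pd.DataFrame) -> None:
    out = judgments.copy()
    out["last_bed"] = out["last_bed"].astype(int)
    out[JUDGMENT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    if df.empty:
        raise SchemaError(f"{path}: cohort file has no records")
    priority = pd.to_numeric(df["priority"], errors="coerce")
    bad = priority.notna() & ~priority.isin([1, 2, 3, 4])
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]
        raise SchemaError(f"{path}: priority outside 1..4 at line(s) {lines}")
    df["priority"] = priority
    for col in ("admitted", "died", "palliative"):
        if not df[col].isin([0, 1, True, False]).all():
            bad = ~df[col].isin([0, 1, True, False])
            lines = [int(i) + 2 for i in df.index[bad]]
            raise SchemaError(f"{path}: {col} must be 0/1 at line(s) {lines}")
        df[col] = df[col].astype(bool)
    return df


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    out = cohort.copy()
    for col in ("admitted", "died", "palliative"):
        out[col] = out[col].astype(int)
    out["priority"] = out["priority"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out[COHORT_COLUMNS].to_csv(path, index=False)
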