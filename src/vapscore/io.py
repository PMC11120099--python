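"""Cohort CSV readers/writers and record ↔ DataFrame conversion.

The cohort CSV dialect is comma-separated UTF-8 with a header row, period
decimal separator and ``NA`` for missing values.  Columns::

    patient_id, vap_confirmed, temperature_c, wbc_per_mm3,
    band_forms_per_mm3, pf_ratio, ards, secretions, radiography,
    microbiology, pct_ng_ml, lus_performed, consolidation_type,
    size_band, laterality, bronchogram

Validation errors name the offending row (1-based, excluding the header)
and column.  Unknown extra columns are carried through untouched.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    Bronchogram,
    ConsolidationType,
    Laterality,
    LusExam,
    Microbiology,
    PatientRecord,
    Radiography,
    Secretions,
    SizeBand,
    ValidationError,
)
from .scores import ScorePanel, ThresholdRule, classify, compute_scores

COHORT_COLUMNS = [
    "patient_id", "vap_confirmed", "temperature_c", "wbc_per_mm3",
    "band_forms_per_mm3", "pf_ratio", "ards", "secretions", "radiography",
    "microbiology", "pct_ng_ml", "lus_performed", "consolidation_type",
    "size_band", "laterality", "bronchogram",
]

SCORE_COLUMNS = ["cpis", "lus_score", "cpis_lus", "cpis_pct", "cpis_plus"]

_ENUMS = {
    "secretions": Secretions,
    "radiography": Radiography,
    "microbiology": Microbiology,
    "consolidation_type": ConsolidationType,
    "size_band": SizeBand,
    "laterality": Laterality,
    "bronchogram": Bronchogram,
}


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value)


def _row_error(row: int, column: str, message: str) -> ValidationError:
    return ValidationError(f"row {row}, column {column!r}: {message}")


def _parse_enum(value, enum_cls, row: int, column: str):
    try:
        return enum_cls(str(value))
    except ValueError:
        valid = sorted(e.value for e in enum_cls)
        raise _row_error(row, column, f"unknown value {value!r}; expected one of {valid}") from None


def _parse_float(value, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise _row_error(row, column, f"non-numeric value {value!r}") from None


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Convert a cohort-schema DataFrame into validated records."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    records = []
    lus_cols = ("consolidation_type", "size_band", "laterality", "bronchogram")
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        lus_performed = bool(int(row["lus_performed"]))
        if lus_performed:
            lus = LusExam(
                consolidation_type=_parse_enum(row["consolidation_type"], ConsolidationType, i, "consolidation_type"),
                size_band=_parse_enum(row["size_band"], SizeBand, i, "size_band"),
                laterality=_parse_enum(row["laterality"], Laterality, i, "laterality"),
                bronchogram=_parse_enum(row["bronchogram"], Bronchogram, i, "bronchogram"),
            )
        else:
            stray = [c for c in lus_cols if not _is_na(row[c])]
            if stray:
                raise _row_error(
                    i, stray[0],
                    "lus_performed=0 but an ultrasound finding is recorded",
                )
            lus = None
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    vap_confirmed=bool(int(row["vap_confirmed"])),
                    temperature=_parse_float(row["temperature_c"], i, "temperature_c"),
                    wbc=_parse_float(row["wbc_per_mm3"], i, "wbc_per_mm3"),
                    band_forms=(
                        0.0 if _is_na(row["band_forms_per_mm3"])
                        else _parse_float(row["band_forms_per_mm3"], i, "band_forms_per_mm3")
                    ),
                    pf_ratio=_parse_float(row["pf_ratio"], i, "pf_ratio"),
                    ards=bool(int(row["ards"])),
                    secretions=_parse_enum(row["secretions"], Secretions, i, "secretions"),
                    microbiology=_parse_enum(row["microbiology"], Microbiology, i, "microbiology"),
                    radiography=(
                        None if _is_na(row["radiography"])
                        else _parse_enum(row["radiography"], Radiography, i, "radiography")
                    ),
                    pct=(
                        None if _is_na(row["pct_ng_ml"])
                        else _parse_float(row["pct_ng_ml"], i, "pct_ng_ml")
                    ),
                    lus=lus,
                )
            )
        except ValidationError as exc:
            if str(exc).startswith("row "):
                raise
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Convert records back to the cohort-CSV DataFrame schema."""
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "vap_confirmed": int(r.vap_confirmed),
            "temperature_c": r.temperature,
            "wbc_per_mm3": r.wbc,
            "band_forms_per_mm3": r.band_forms,
            "pf_ratio": r.pf_ratio,
            "ards": int(r.ards),
            "secretions": r.secretions.value,
            "radiography": r.radiography.value if r.radiography is not None else pd.NA,
            "microbiology": r.microbiology.value,
            "pct_ng_ml": r.pct if r.pct is not None else pd.NA,
            "lus_performed": int(r.lus is not None),
            "consolidation_type": r.lus.consolidation_type.value if r.lus else pd.NA,
            "size_band": r.lus.size_band.value if r.lus else pd.NA,
            "laterality": r.lus.laterality.value if r.lus else pd.NA,
            "bronchogram": r.lus.bronchogram.value if r.lus else pd.NA,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV into validated records."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True, dtype=object)
    return frame_to_records(df)


def write_cohort(cohort, path) -> None:
    """Write a cohort (records or DataFrame) as a cohort CSV."""
    df = cohort if isinstance(cohort, pd.DataFrame) else records_to_frame(cohort)
    df.to_csv(path, index=False, na_rep="NA")


def score_frame(
    df: pd.DataFrame,
    rules: Optional[Sequence[ThresholdRule]] = None,
    lus_table=None,
) -> pd.DataFrame:
    """Append the five score columns (and rule predictions) to a cohort.

    Undefined scores become ``NA`` (nullable integer columns); each rule
    adds a ``pred_<rule>`` column with positive/negative/undetermined.
    """
    from .scores import DEFAULT_LUS_TABLE

    records = frame_to_records(df)
    table = lus_table if lus_table is not None else DEFAULT_LUS_TABLE
    panels = [compute_scores(r, table) for r in records]
    out = df.copy()
    for col, attr in zip(SCORE_COLUMNS, ("cpis", "lus_score", "cpis_lus", "cpis_pct", "cpis_plus")):
        out[col] = pd.array([getattr(p, attr) for p in panels], dtype="Int64")
    if rules:
        for rule in rules:
            out[f"pred_{rule.label}"] = [classify(p, rule) for p in panels]
    return out
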