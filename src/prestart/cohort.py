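"""Participant data model and delimited-file I/O.

One row per adolescent (12-14 years): demographics, anthropometry, a triplet
of blood-pressure readings, point-of-care biochemistry, perinatal history,
lifestyle questionnaire summaries, parental BMI/ethnicity and up to three
clinician risk ratings.  Missing data is first-class: a blank cell becomes
``None`` (numerics) or :class:`~prestart.tristate.TriState.UNKNOWN`
(flags), never zero or false.

Units are fixed by the schema: cm, kg/m², mmol/L, %, ml, minutes, hours,
g/month.  Age is completed years (the waist cut points are indexed by
integer age and sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .tristate import TriState, format_tristate, parse_tristate

#: country strata of the evaluation study; the enum is extensible — any
#: non-empty string is accepted, these are the documented defaults.
COUNTRIES = ("UK", "Germany", "Portugal", "Spain", "Greece")

SEXES = ("male", "female")

#: columns that must be present and non-blank in every input file
MANDATORY_COLUMNS = ("id", "country", "sex", "age_years")

#: numeric columns (blank -> None)
NUMERIC_COLUMNS = (
    "bmi",
    "bmi_z",
    "waist_cm",
    "screen_hours_per_day",
    "physical_activity_min_per_day",
    "fruit_veg_portions_per_day",
    "sugary_drink_ml_per_day",
    "infant_weight_gain_g_per_month",
    "parent1_bmi",
    "parent2_bmi",
    "glucose_mmol_l",
    "hba1c_pct",
    "total_chol_mmol_l",
    "ldl_mmol_l",
    "triglycerides_mmol_l",
)

#: tri-state flag columns (blank -> unknown)
TRISTATE_COLUMNS = (
    "breast_fed",
    "first_degree_fh_diabetes",
    "second_degree_fh_diabetes",
    "ethnicity_caucasian",
    "acanthosis_nigricans",
    "fatty_liver",
    "pcos",
    "prediabetes_flag",
    "sga_flag",
    "parent1_white_european",
    "parent2_white_european",
    "fasting",
    "rater1_high",
    "rater2_high",
    "rater3_high",
)

#: blood-pressure triplet stored as six columns; trailing blanks mean
#: fewer than three readings were taken
BP_COLUMNS = tuple(
    f"{part}{i}" for i in (1, 2, 3) for part in ("systolic", "diastolic")
)

CANONICAL_COLUMNS: Tuple[str, ...] = (
    MANDATORY_COLUMNS + NUMERIC_COLUMNS + BP_COLUMNS + TRISTATE_COLUMNS
)


@dataclass
class ParticipantRecord:
    """One adolescent's raw measurements, history and rater labels."""

    id: str
    country: str
    sex: str
    age_years: int
    bmi: Optional[float] = None
    bmi_z: Optional[float] = None
    waist_cm: Optional[float] = None
    screen_hours_per_day: Optional[float] = None
    physical_activity_min_per_day: Optional[float] = None
    fruit_veg_portions_per_day: Optional[float] = None
    sugary_drink_ml_per_day: Optional[float] = None
    infant_weight_gain_g_per_month: Optional[float] = None
    parent1_bmi: Optional[float] = None
    parent2_bmi: Optional[float] = None
    glucose_mmol_l: Optional[float] = None
    hba1c_pct: Optional[float] = None
    total_chol_mmol_l: Optional[float] = None
    ldl_mmol_l: Optional[float] = None
    triglycerides_mmol_l: Optional[float] = None
    bp_readings: List[Tuple[float, float]] = field(default_factory=list)
    breast_fed: TriState = TriState.UNKNOWN
    first_degree_fh_diabetes: TriState = TriState.UNKNOWN
    second_degree_fh_diabetes: TriState = TriState.UNKNOWN
    ethnicity_caucasian: TriState = TriState.UNKNOWN
    acanthosis_nigricans: TriState = TriState.UNKNOWN
    fatty_liver: TriState = TriState.UNKNOWN
    pcos: TriState = TriState.UNKNOWN
    prediabetes_flag: TriState = TriState.UNKNOWN
    sga_flag: TriState = TriState.UNKNOWN
    parent1_white_european: TriState = TriState.UNKNOWN
    parent2_white_european: TriState = TriState.UNKNOWN
    fasting: TriState = TriState.UNKNOWN
    rater1_high: TriState = TriState.UNKNOWN
    rater2_high: TriState = TriState.UNKNOWN
    rater3_high: TriState = TriState.UNKNOWN

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.country:
            raise ValidationError(f"record {self.id}: country must be non-empty")
        if self.sex not in SEXES:
            raise ValidationError(
                f"record {self.id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.age_years not in (12, 13, 14):
            raise ValidationError(
                f"record {self.id}: age_years must be 12, 13 or 14, "
                f"got {self.age_years!r}"
            )
        for col in NUMERIC_COLUMNS:
            if col == "bmi_z":   # an SD score; negative is meaningful
                continue
            value = getattr(self, col)
            if value is not None and not value > 0:
                raise ValidationError(
                    f"record {self.id}: {col} must be strictly positive "
                    f"when known, got {value!r}"
                )
        if len(self.bp_readings) > 3:
            raise ValidationError(
                f"record {self.id}: at most 3 blood-pressure readings allowed"
            )
        for sys_bp, dia_bp in self.bp_readings:
            if not (sys_bp > 0 and dia_bp > 0):
                raise ValidationError(
                    f"record {self.id}: blood pressures must be positive"
                )
            if not sys_bp > dia_bp:
                raise ValidationError(
                    f"record {self.id}: systolic ({sys_bp}) must exceed "
                    f"diastolic ({dia_bp})"
                )


def _parse_float(cell: object) -> Optional[float]:
    if cell is None:
        return None
    text = str(cell).strip()
    if text == "" or text.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(text)
    except ValueError:
        # unparseable cells become unknown, never zero
        return None


def _parse_int(cell: object, column: str, row_id: str) -> int:
    value = _parse_float(cell)
    if value is None or value != int(value):
        raise ValidationError(
            f"record {row_id}: column {column!r} must be an integer, got {cell!r}"
        )
    return int(value)


def record_from_row(row: Mapping[str, object]) -> ParticipantRecord:
    """Build a record from one row of string-valued cells."""
    rid = str(row.get("id", "")).strip()
    kwargs: Dict[str, object] = {
        "id": rid,
        "country": str(row.get("country", "")).strip(),
        "sex": str(row.get("sex", "")).strip().lower(),
        "age_years": _parse_int(row.get("age_years"), "age_years", rid),
    }
    for col in NUMERIC_COLUMNS:
        kwargs[col] = _parse_float(row.get(col))
    for col in TRISTATE_COLUMNS:
        kwargs[col] = parse_tristate(row.get(col))
    readings: List[Tuple[float, float]] = []
    for i in (1, 2, 3):
        sys_bp = _parse_float(row.get(f"systolic{i}"))
        dia_bp = _parse_float(row.get(f"diastolic{i}"))
        if sys_bp is not None and dia_bp is not None:
            readings.append((sys_bp, dia_bp))
    kwargs["bp_readings"] = readings
    return ParticipantRecord(**kwargs)  # type: ignore[arg-type]


def record_to_row(record: ParticipantRecord) -> Dict[str, str]:
    """Serialise a record to string cells; unknowns become blanks."""
    row: Dict[str, str] = {
        "id": record.id,
        "country": record.country,
        "sex": record.sex,
        "age_years": str(record.age_years),
    }
    for col in NUMERIC_COLUMNS:
        value = getattr(record, col)
        row[col] = "" if value is None else repr(float(value))
    for i in (1, 2, 3):
        if i <= len(record.bp_readings):
            sys_bp, dia_bp = record.bp_readings[i - 1]
            row[f"systolic{i}"] = repr(float(sys_bp))
            row[f"diastolic{i}"] = repr(float(dia_bp))
        else:
            row[f"systolic{i}"] = ""
            row[f"diastolic{i}"] = ""
    for col in TRISTATE_COLUMNS:
        row[col] = format_tristate(getattr(record, col))
    return row


def read_cohort(
    path,
    delimiter: str = ",",
    aliases: Optional[Mapping[str, str]] = None,
    validate: bool = True,
) -> List[ParticipantRecord]:
    """Read a delimited cohort file into an ordered list of records.

    Parameters
    ----------
    path
        CSV (or other delimited) file with a header row naming a superset
        of the canonical schema.
    delimiter
        Field separator, default comma.
    aliases
        Optional ``{file_header: canonical_name}`` map for files whose
        headers differ from the canonical schema.
    validate
        Check record invariants and id uniqueness (default on).

    Raises
    ------
    SchemaError
        If a mandatory column (id, country, sex, age_years) is missing.
    ValidationError
        On duplicate ids or invariant violations.
    """
    frame = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    if aliases:
        frame = frame.rename(columns=dict(aliases))
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s): {', '.join(missing)}"
        )
    records = [record_from_row(row) for row in frame.to_dict(orient="records")]
    if validate:
        seen = set()
        for record in records:
            record.validate()
            if record.id in seen:
                raise ValidationError(f"duplicate id: {record.id}")
            seen.add(record.id)
    return records


def write_cohort(
    records: Sequence[ParticipantRecord], path, delimiter: str = ","
) -> None:
    """Write records to a delimited file; re-reading reproduces them.

    An empty collection produces a header-only file.  Unknown values are
    written as blank cells, never as "0".
    """
    for record in records:
        record.validate()
    rows = [record_to_row(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    frame.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def summarize_cohort(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Per-country and overall cohort summary.

    Returns a DataFrame indexed by statistic with one column per country
    plus ``Total``: n, % male, and per numeric field the mean, SD and
    missing count computed over known values only.
    """
    if not records:
        raise ValidationError("summarize_cohort requires at least one record")
    countries = list(dict.fromkeys(r.country for r in records))
    groups = {c: [r for r in records if r.country == c] for c in countries}
    groups["Total"] = list(records)

    stats: Dict[str, Dict[str, float]] = {}
    for name, group in groups.items():
        col: Dict[str, float] = {"n": len(group)}
        col["pct_male"] = 100.0 * sum(r.sex == "male" for r in group) / len(group)
        for numeric in NUMERIC_COLUMNS:
            values = [
                getattr(r, numeric) for r in group
                if getattr(r, numeric) is not None
            ]
            if values:
                col[f"{numeric}_mean"] = float(np.mean(values))
                col[f"{numeric}_sd"] = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
            else:
                col[f"{numeric}_mean"] = float("nan")
                col[f"{numeric}_sd"] = float("nan")
            col[f"{numeric}_n_known"] = len(values)
            col[f"{numeric}_missing"] = len(group) - len(values)
        stats[name] = col
    return pd.DataFrame(stats)
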