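"""Delimited-file schemas, cohort reading/writing, and pipeline runners.

The canonical dialect is comma-separated UTF-8 with a header row, decimal
points, and missing values as empty fields or ``NA``; a tab dialect is
available by flag.  Row-level validation errors are collected with their
row numbers and either reported together (default) or raised on first
occurrence (strict mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementReport, compare_methods, format_report_table
from .estimators import (
    DEFAULT_SLOPE_MIN,
    CombinedRule,
    LemConstants,
    MrmCoefficients,
    estimate_combined,
    estimate_lem,
    estimate_mrm,
)
from .step_test import HrIndexUndefined, MaxHrFormula, compute_hr_index
from .types import (
    Participant,
    StepTestRecord,
    TreadmillRecord,
    ValidationError,
    make_participant,
    normalize_sex,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "CohortRow",
    "ReadResult",
    "read_cohort",
    "write_cohort",
    "run_estimate",
    "run_validate",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "id",
    "age",
    "sex",
    "pa_score",
    "hr_rest",
    "hr_ex1",
    "hr_ex2",
    "hr_ex3",
    "hr_rec1",
    "hr_rec2",
)
#: One of bmi or (height_cm, weight_kg) must additionally be present.
OPTIONAL_COLUMNS = (
    "bmi",
    "height_cm",
    "weight_kg",
    "stage3_skipped",
    "rpe_end_stage2",
    "vo2max_measured",
    "rer_max",
    "hr_max_observed",
    "rpe_max",
    "plateau",
)

_NA_TOKENS = {"", "na", "nan", "none"}
_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


def _parse_optional_float(value: object) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip().lower() in _NA_TOKENS:
        return None
    return float(value)


def _parse_optional_bool(value: object) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _NA_TOKENS:
        return None
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValidationError(f"unparseable boolean: {value!r}")


@dataclass(frozen=True)
class CohortRow:
    """One validated input row."""

    participant: Participant
    step: StepTestRecord
    treadmill: Optional[TreadmillRecord]
    vo2max_measured: Optional[float]


@dataclass
class ReadResult:
    rows: list[CohortRow] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)  # (row number, message)

    @property
    def n_ok(self) -> int:
        return len(self.rows)


def _row_to_records(row: pd.Series) -> CohortRow:
    bmi = _parse_optional_float(row.get("bmi"))
    height = _parse_optional_float(row.get("height_cm"))
    weight = _parse_optional_float(row.get("weight_kg"))
    participant = make_participant(
        id=row["id"],
        age=float(row["age"]),
        sex=normalize_sex(row["sex"]),
        pa_score=float(row["pa_score"]),
        height_cm=height,
        weight_kg=weight,
        bmi=bmi,
    )
    skipped = _parse_optional_bool(row.get("stage3_skipped")) or False
    step = StepTestRecord(
        hr_rest=float(row["hr_rest"]),
        hr_ex1=float(row["hr_ex1"]),
        hr_ex2=float(row["hr_ex2"]),
        hr_ex3=_parse_optional_float(row.get("hr_ex3")),
        hr_rec1=float(row["hr_rec1"]),
        hr_rec2=float(row["hr_rec2"]),
        stage3_skipped=skipped,
        rpe_end_stage2=_parse_optional_float(row.get("rpe_end_stage2")),
    )
    measured = _parse_optional_float(row.get("vo2max_measured"))
    rer = _parse_optional_float(row.get("rer_max"))
    hr_max = _parse_optional_float(row.get("hr_max_observed"))
    rpe_max = _parse_optional_float(row.get("rpe_max"))
    treadmill = None
    if measured is not None and rer is not None and hr_max is not None and rpe_max is not None:
        treadmill = TreadmillRecord(
            vo2_peak_30s=measured,
            rer_max=rer,
            hr_max_observed=hr_max,
            rpe_max=rpe_max,
            plateau=_parse_optional_bool(row.get("plateau")),
        )
    return CohortRow(
        participant=participant,
        step=step,
        treadmill=treadmill,
        vo2max_measured=measured,
    )


def read_cohort(
    path: str | Path,
    *,
    sep: str = ",",
    strict: bool = False,
) -> ReadResult:
    """Read and validate a cohort file.

    Column order is free; unknown columns are ignored.  Returns validated
    rows plus (row number, message) pairs for rows that failed; in strict
    mode the first failure raises instead.
    """
    frame = pd.read_csv(path, sep=sep, dtype={"id": str},
                        float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if not ({"bmi"} <= set(frame.columns) or {"height_cm", "weight_kg"} <= set(frame.columns)):
        raise ValidationError("need a bmi column or both height_cm and weight_kg")
    if frame["id"].duplicated().any():
        dupes = frame.loc[frame["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate ids: {dupes}")

    result = ReadResult()
    for i, (_, row) in enumerate(frame.iterrows(), start=2):  # 1-based + header
        try:
            result.rows.append(_row_to_records(row))
        except (ValidationError, ValueError) as exc:
            if strict:
                raise ValidationError(f"row {i}: {exc}") from exc
            result.errors.append((i, str(exc)))
    if result.errors:
        logger.warning(
            "%d of %d rows failed validation", len(result.errors), len(frame)
        )
    return result


def write_cohort(frame: pd.DataFrame, path: str | Path, *, sep: str = ",") -> None:
    """Write a cohort (or results) table in the canonical dialect."""
    frame.to_csv(path, sep=sep, index=False, na_rep="")


def run_estimate(
    rows: Sequence[CohortRow],
    methods: Sequence[str] = ("mrm", "lem", "combined"),
    *,
    coefs: MrmCoefficients = MrmCoefficients(),
    constants: LemConstants = LemConstants(),
    rule: CombinedRule = CombinedRule(),
    formula: MaxHrFormula = MaxHrFormula.TANAKA,
    slope_min: float = DEFAULT_SLOPE_MIN,
) -> pd.DataFrame:
    """Per-row estimates for each requested method, with intermediates.

    Missing results stay in the output as empty values with a reason column,
    keeping downstream joins aligned.
    """
    unknown = set(methods) - {"mrm", "lem", "combined"}
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")
    out_rows = []
    n_missing = 0
    for row in rows:
        p, s = row.participant, row.step
        rec: dict[str, object] = {"id": p.id}
        try:
            hr_index = compute_hr_index(s)
        except HrIndexUndefined:
            hr_index = None
        rec["hr_index"] = hr_index
        if "mrm" in methods:
            res = estimate_mrm(p, hr_index, coefs)
            rec["mrm"] = res.evo2max
            rec["mrm_reason"] = res.reason
            n_missing += res.is_missing
        if "lem" in methods:
            res = estimate_lem(p, s, constants, formula, slope_min)
            rec["lem"] = res.evo2max
            rec["lem_reason"] = res.reason
            rec["lem_slope"] = res.lem_slope
            rec["lem_intercept"] = res.lem_intercept
            rec["predicted_max_hr"] = res.predicted_max_hr
            n_missing += res.is_missing
        if "combined" in methods:
            res = estimate_combined(p, s, rule, coefs, constants, formula, slope_min)
            rec["combined"] = res.evo2max
            rec["combined_reason"] = res.reason
            rec["switched_to_lem"] = res.switched_to_lem
            n_missing += res.is_missing
        if row.vo2max_measured is not None:
            rec["vo2max_measured"] = row.vo2max_measured
        out_rows.append(rec)
    if n_missing:
        logger.info("%d missing estimates across %d rows", n_missing, len(out_rows))
    return pd.DataFrame(out_rows)


def run_validate(
    frame: pd.DataFrame,
    measured: str = "vo2max_measured",
    methods: Sequence[str] = ("mrm", "lem", "combined"),
) -> tuple[dict[str, AgreementReport], str]:
    """Agreement reports per estimate column plus a text-table rendering.

    Methods with fewer than 3 complete pairs are skipped with a warning.
    """
    if measured not in frame.columns:
        raise ValidationError(f"measured column {measured!r} missing")
    available = [m for m in methods if m in frame.columns]
    if not available:
        raise ValidationError("no estimate columns present")
    usable = []
    for m in available:
        n_complete = int((frame[measured].notna() & frame[m].notna()).sum())
        if n_complete < 3:
            logger.warning("method %s: only %d complete pairs; skipped", m, n_complete)
        else:
            usable.append(m)
    reports = compare_methods(frame, measured=measured, methods=usable)
    return reports, format_report_table(reports)
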