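"""The three VO2max estimators.

* **MRM** — a fixed-coefficient multiple regression on age, sex, BMI,
  physical-activity score and the step-test HR index.
* **LEM** — a per-subject ordinary-least-squares line of stage HR (y) on
  predetermined stage VO2 constants (x), extrapolated to the subject's
  age-predicted maximal HR (Tanaka, 208 - 0.7*age) and inverted for VO2.
* **Combined** — MRM first; results at or above a fitness cutoff
  (default 45.0 mL·kg⁻¹·min⁻¹) are recalculated with the LEM, which does
  not share the regression's compression of the upper range.

The regression direction of the LEM is HR on VO2 followed by algebraic
inversion, matching the protocol's scatter-plot construction (constant VO2
on the x-axis, HR on the y-axis); regressing VO2 on HR would differ
whenever the points are not collinear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .step_test import (
    HR_INDEX_SKIP_REASON,
    HrIndexUndefined,
    MaxHrFormula,
    compute_hr_index,
    predicted_max_hr,
)
from .types import (
    EstimateResult,
    Method,
    Participant,
    Sex,
    StepTestRecord,
    ValidationError,
)

__all__ = [
    "MrmCoefficients",
    "LemConstants",
    "CombinedRule",
    "DEFAULT_SLOPE_MIN",
    "estimate_mrm",
    "estimate_mrm_from_record",
    "fit_lem_line",
    "estimate_lem",
    "estimate_combined",
]

#: Minimum acceptable LEM slope, bpm per mL·kg⁻¹·min⁻¹.  A near-flat or
#: negative HR-vs-workload line makes the extrapolation meaningless (the
#: inversion divides by the slope); such fits return a missing result.
DEFAULT_SLOPE_MIN = 0.1


@dataclass(frozen=True)
class MrmCoefficients:
    """Published regression coefficients, mL·kg⁻¹·min⁻¹ per predictor unit.

    eVO2max = intercept + age_coef*age + sex_coef*I(male) + bmi_coef*BMI
            + pa_coef*PA + hr_index_coef*HRindex

    The defaults are the validated equation; override them only as a full
    set — the coefficients were fit jointly and are meaningless piecemeal.
    """

    intercept: float = 64.22
    age_coef: float = -0.23
    sex_coef: float = 5.74
    bmi_coef: float = -0.57
    pa_coef: float = 0.19
    hr_index_coef: float = -0.18


@dataclass(frozen=True)
class LemConstants:
    """Per-sex stage VO2 constants, mL·kg⁻¹·min⁻¹, in protocol order
    (rest, exercise 1-3, recovery 1-2)."""

    female: tuple[float, ...] = (4.0, 13.0, 19.0, 22.0, 17.0, 8.0)
    male: tuple[float, ...] = (4.0, 14.0, 20.0, 23.0, 18.0, 8.0)

    def __post_init__(self) -> None:
        for name in ("female", "male"):
            vals = getattr(self, name)
            if len(vals) != 6 or any(v <= 0 for v in vals):
                raise ValidationError(
                    f"{name} stage constants must be 6 positive values"
                )

    def for_sex(self, sex: Sex) -> dict[str, float]:
        vals = self.male if sex is Sex.MALE else self.female
        return dict(zip(("rest", "ex1", "ex2", "ex3", "rec1", "rec2"), vals))


@dataclass(frozen=True)
class CombinedRule:
    """Switching rule of the combined estimator.

    MRM estimates meeting the cutoff comparison are recalculated with the
    LEM.  The default comparison is inclusive (>= 45.0); a strict version is
    available because the boundary must be deterministic even though it is
    measure-zero in practice.
    """

    cutoff: float = 45.0
    strict: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")

    def triggers(self, mrm_value: float) -> bool:
        return mrm_value > self.cutoff if self.strict else mrm_value >= self.cutoff


def estimate_mrm(
    p: Participant,
    hr_index: Optional[float],
    coefs: MrmCoefficients = MrmCoefficients(),
) -> EstimateResult:
    """Regression estimate; exact linear evaluation with no clipping.

    ``hr_index`` is ``None`` when stage 3 was skipped, in which case the
    result is missing with a reason code rather than an exception: a skipped
    stage is a legitimate protocol outcome, not a data error.
    """
    if hr_index is None:
        return EstimateResult(method=Method.MRM, reason=HR_INDEX_SKIP_REASON)
    value = (
        coefs.intercept
        + coefs.age_coef * p.age
        + coefs.sex_coef * p.sex.indicator
        + coefs.bmi_coef * p.bmi
        + coefs.pa_coef * p.pa_score
        + coefs.hr_index_coef * hr_index
    )
    return EstimateResult(method=Method.MRM, evo2max=value, hr_index=hr_index)


def estimate_mrm_from_record(
    p: Participant,
    record: StepTestRecord,
    coefs: MrmCoefficients = MrmCoefficients(),
) -> EstimateResult:
    """Convenience wrapper computing the HR index from a step-test record."""
    try:
        hr_index = compute_hr_index(record)
    except HrIndexUndefined:
        hr_index = None
    return estimate_mrm(p, hr_index, coefs)


def fit_lem_line(
    record: StepTestRecord,
    sex: Sex,
    constants: LemConstants = LemConstants(),
) -> tuple[float, float]:
    """OLS line of stage HR (y, bpm) on stage VO2 constants (x).

    Uses the stages present on the record: all six, or five when stage 3 was
    skipped (its constant is dropped with it).  Returns (slope, intercept).
    """
    stage_vo2 = constants.for_sex(sex)
    pairs = record.stage_heart_rates()
    x = np.array([stage_vo2[name] for name, _ in pairs], dtype=float)
    y = np.array([hr for _, hr in pairs], dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValidationError(
            "LEM fit requires at least 2 distinct stage VO2 values"
        )
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def estimate_lem(
    p: Participant,
    record: StepTestRecord,
    constants: LemConstants = LemConstants(),
    formula: MaxHrFormula = MaxHrFormula.TANAKA,
    slope_min: float = DEFAULT_SLOPE_MIN,
) -> EstimateResult:
    """Extrapolation estimate: invert the fitted line at the age-predicted
    maximal HR.

    evo2max = (predicted_max_hr(age) - intercept) / slope

    Fits with slope below ``slope_min`` and non-positive extrapolations are
    reported as missing with a reason, never silently clipped.
    """
    slope, intercept = fit_lem_line(record, p.sex, constants)
    max_hr = predicted_max_hr(p.age, formula)
    if slope < slope_min:
        return EstimateResult(
            method=Method.LEM,
            reason=(
                f"non-positive or degenerate slope ({slope:.4g} bpm per "
                f"mL·kg⁻¹·min⁻¹ < {slope_min:g})"
            ),
            lem_slope=slope,
            lem_intercept=intercept,
            predicted_max_hr=max_hr,
        )
    value = (max_hr - intercept) / slope
    if value <= 0:
        return EstimateResult(
            method=Method.LEM,
            reason=f"non-positive extrapolated VO2max ({value:.4g})",
            lem_slope=slope,
            lem_intercept=intercept,
            predicted_max_hr=max_hr,
        )
    return EstimateResult(
        method=Method.LEM,
        evo2max=value,
        lem_slope=slope,
        lem_intercept=intercept,
        predicted_max_hr=max_hr,
    )


def estimate_combined(
    p: Participant,
    record: StepTestRecord,
    rule: CombinedRule = CombinedRule(),
    coefs: MrmCoefficients = MrmCoefficients(),
    constants: LemConstants = LemConstants(),
    formula: MaxHrFormula = MaxHrFormula.TANAKA,
    slope_min: float = DEFAULT_SLOPE_MIN,
) -> EstimateResult:
    """Combined estimate: MRM, recalculated with the LEM above the cutoff.

    The returned value is bit-identical to one of the two legs; which leg is
    determined solely by comparing the MRM value to the rule's cutoff.  If
    the LEM leg fails after switching, the result is missing with the leg's
    reason — it does not fall back to the MRM value it just rejected.
    """
    mrm = estimate_mrm_from_record(p, record, coefs)
    if mrm.is_missing:
        return EstimateResult(
            method=Method.COMBINED,
            reason=f"MRM leg: {mrm.reason}",
            switched_to_lem=False,
        )
    if not rule.triggers(mrm.evo2max):
        return EstimateResult(
            method=Method.COMBINED,
            evo2max=mrm.evo2max,
            hr_index=mrm.hr_index,
            switched_to_lem=False,
        )
    lem = estimate_lem(p, record, constants, formula, slope_min)
    if lem.is_missing:
        return EstimateResult(
            method=Method.COMBINED,
            reason=f"LEM leg after switch: {lem.reason}",
            hr_index=mrm.hr_index,
            lem_slope=lem.lem_slope,
            lem_intercept=lem.lem_intercept,
            predicted_max_hr=lem.predicted_max_hr,
            switched_to_lem=True,
        )
    return EstimateResult(
        method=Method.COMBINED,
        evo2max=lem.evo2max,
        hr_index=mrm.hr_index,
        lem_slope=lem.lem_slope,
        lem_intercept=lem.lem_intercept,
        predicted_max_hr=lem.predicted_max_hr,
        switched_to_lem=True,
    )
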