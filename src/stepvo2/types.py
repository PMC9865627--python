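"""Core domain records for step-test-based VO2max estimation.

Units are fixed package-wide: age in years, height in cm, weight in kg,
BMI in kg·m⁻², heart rates in beats·min⁻¹ (bpm), oxygen uptake in
mL·kg⁻¹·min⁻¹, physical-activity questionnaire score in points (0–44),
perceived exertion on the Borg 6–20 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Sex",
    "Method",
    "ValidationError",
    "StudyRangeWarning",
    "Participant",
    "StepTestRecord",
    "TreadmillRecord",
    "EstimateResult",
    "PairedCohort",
    "make_participant",
    "normalize_sex",
    "HR_RANGE",
    "PA_RANGE",
    "RPE_RANGE",
    "STUDY_AGE_RANGE",
]

#: Plausibility window for any heart-rate field, bpm.  Deliberately generous:
#: it rejects unit mistakes (e.g. RR intervals in ms) without excluding
#: athletes at either extreme of the physiological range.
HR_RANGE = (30.0, 230.0)

#: Physical-activity questionnaire total score range, points.
PA_RANGE = (0.0, 44.0)

#: Borg rating of perceived exertion scale.
RPE_RANGE = (6.0, 20.0)

#: Age range of the population the fixed regression coefficients were
#: validated on.  Ages outside it are accepted with a warning, not an error:
#: the equations are formally evaluable at any adult age.
STUDY_AGE_RANGE = (30.0, 60.0)


class ValidationError(ValueError):
    """A record violates a declared physiological or structural invariant."""


class StudyRangeWarning(UserWarning):
    """Input is valid but outside the range the estimators were validated on."""


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"

    @property
    def indicator(self) -> int:
        """0/1 dummy coding used inside the regression estimator (men = 1)."""
        return 1 if self is Sex.MALE else 0


class Method(str, Enum):
    MRM = "mrm"
    LEM = "lem"
    COMBINED = "combined"


_SEX_TOKENS = {
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "w": Sex.FEMALE,
    "woman": Sex.FEMALE,
    "women": Sex.FEMALE,
    "0": Sex.FEMALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
    "man": Sex.MALE,
    "men": Sex.MALE,
    "1": Sex.MALE,
}


def normalize_sex(token: object) -> Sex:
    """Map file encodings (F/M, 0/1, female/male, ...) onto the enumeration.

    The 0/1 coding follows the regression model's dummy variable
    (women = 0, men = 1), so numeric columns round-trip unambiguously.
    """
    if isinstance(token, Sex):
        return token
    if isinstance(token, (int, np.integer)) or (
        isinstance(token, float) and float(token).is_integer()
    ):
        token = str(int(token))
    key = str(token).strip().lower()
    if key not in _SEX_TOKENS:
        raise ValidationError(f"unrecognized sex token: {token!r}")
    return _SEX_TOKENS[key]


def _check_hr(name: str, value: Optional[float]) -> None:
    if value is None:
        return
    lo, hi = HR_RANGE
    if not (lo <= value <= hi):
        raise ValidationError(f"{name}={value} bpm outside plausible range [{lo}, {hi}]")


@dataclass(frozen=True)
class Participant:
    """Demographic and anthropometric predictors for one subject.

    ``bmi`` must be present; use :func:`make_participant` to derive it from
    height and weight.  If height and weight are also stored they must be
    consistent with ``bmi`` to within 1e-9.
    """

    id: str
    age: float
    sex: Sex
    pa_score: float
    bmi: float
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        lo, hi = PA_RANGE
        if not (lo <= self.pa_score <= hi):
            raise ValidationError(
                f"pa_score={self.pa_score} outside [{lo:g}, {hi:g}] points"
            )
        if self.bmi is None or not math.isfinite(self.bmi) or self.bmi <= 0:
            raise ValidationError(f"bmi must be positive and finite, got {self.bmi}")
        if self.height_cm is not None and self.weight_kg is not None:
            derived = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(derived - self.bmi) > 1e-9:
                raise ValidationError(
                    f"bmi={self.bmi} inconsistent with height/weight (derived {derived})"
                )
        a_lo, a_hi = STUDY_AGE_RANGE
        if not (a_lo <= self.age <= a_hi):
            warnings.warn(
                f"participant {self.id}: age {self.age} outside the validated "
                f"range [{a_lo:g}, {a_hi:g}] years; estimates are extrapolations",
                StudyRangeWarning,
                stacklevel=2,
            )


def make_participant(
    id: str,
    age: float,
    sex: object,
    pa_score: float,
    *,
    height_cm: Optional[float] = None,
    weight_kg: Optional[float] = None,
    bmi: Optional[float] = None,
) -> Participant:
    """Validate raw fields and build a :class:`Participant`.

    BMI is derived as weight (kg) divided by squared height (m) when not
    given directly; at least one of ``bmi`` or (``height_cm``, ``weight_kg``)
    is required.
    """
    if bmi is None:
        if height_cm is None or weight_kg is None:
            raise ValidationError(
                "either bmi or both height_cm and weight_kg are required"
            )
        if height_cm <= 0 or weight_kg <= 0:
            raise ValidationError("height_cm and weight_kg must be positive")
        bmi = weight_kg / (height_cm / 100.0) ** 2
    return Participant(
        id=str(id),
        age=float(age),
        sex=normalize_sex(sex),
        pa_score=float(pa_score),
        bmi=float(bmi),
        height_cm=None if height_cm is None else float(height_cm),
        weight_kg=None if weight_kg is None else float(weight_kg),
    )


@dataclass(frozen=True)
class StepTestRecord:
    """Heart rates over the six step-test stages.

    The protocol is three 1-min stepping stages followed by two 1-min seated
    recovery stages; resting HR is taken seated before stage 1 (the
    extrapolation estimator needs all six points).  Stage 3 may be skipped by
    protocol for subjects already near maximal exertion at the end of stage 2,
    in which case ``hr_ex3`` is absent and ``stage3_skipped`` is set.
    """

    hr_rest: float
    hr_ex1: float
    hr_ex2: float
    hr_rec1: float
    hr_rec2: float
    hr_ex3: Optional[float] = None
    stage3_skipped: bool = False
    rpe_end_stage2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("hr_rest", "hr_ex1", "hr_ex2", "hr_ex3", "hr_rec1", "hr_rec2"):
            _check_hr(name, getattr(self, name))
        if self.stage3_skipped and self.hr_ex3 is not None:
            raise ValidationError("hr_ex3 must be absent when stage3_skipped")
        if not self.stage3_skipped and self.hr_ex3 is None:
            raise ValidationError("hr_ex3 missing but stage3_skipped is not set")
        if self.rpe_end_stage2 is not None:
            lo, hi = RPE_RANGE
            if not (lo <= self.rpe_end_stage2 <= hi):
                raise ValidationError(
                    f"rpe_end_stage2={self.rpe_end_stage2} outside Borg [{lo:g}, {hi:g}]"
                )

    def stage_heart_rates(self) -> tuple[tuple[str, float], ...]:
        """Available (stage name, HR) pairs in protocol order."""
        stages = [("rest", self.hr_rest), ("ex1", self.hr_ex1), ("ex2", self.hr_ex2)]
        if not self.stage3_skipped:
            stages.append(("ex3", self.hr_ex3))
        stages += [("rec1", self.hr_rec1), ("rec2", self.hr_rec2)]
        return tuple(stages)


@dataclass(frozen=True)
class TreadmillRecord:
    """Criterion treadmill test summary for one subject.

    ``vo2_peak_30s`` is the highest 30-s average oxygen uptake; it counts as
    a true maximum only when enough attainment criteria are met (see
    :func:`stepvo2.step_test.verify_max_effort`).  ``plateau`` may be unknown
    (``None``), which counts as the criterion being unmet.
    """

    vo2_peak_30s: float
    rer_max: float
    hr_max_observed: float
    rpe_max: float
    plateau: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.vo2_peak_30s <= 0:
            raise ValidationError("vo2_peak_30s must be positive")
        if self.rer_max <= 0:
            raise ValidationError("rer_max must be positive")
        _check_hr("hr_max_observed", self.hr_max_observed)


@dataclass(frozen=True)
class EstimateResult:
    """One estimator's output with its intermediate quantities.

    ``evo2max`` is ``None`` when the method could not produce a value, in
    which case ``reason`` explains why.  Intermediates are populated per
    method: ``hr_index`` on the regression path, line parameters and the
    age-predicted maximal HR on the extrapolation path, and
    ``switched_to_lem`` on the combined path.
    """

    method: Method
    evo2max: Optional[float] = None
    reason: Optional[str] = None
    hr_index: Optional[float] = None
    lem_slope: Optional[float] = None
    lem_intercept: Optional[float] = None
    predicted_max_hr: Optional[float] = None
    switched_to_lem: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.evo2max is None and not self.reason:
            raise ValidationError("missing evo2max requires a reason code")
        if self.method is Method.COMBINED and self.switched_to_lem is None:
            raise ValidationError("combined result requires switched_to_lem")

    @property
    def is_missing(self) -> bool:
        return self.evo2max is None


class PairedCohort:
    """Matched measured/estimated VO2max vectors with no missing entries."""

    __slots__ = ("ids", "measured", "estimated")

    def __init__(
        self,
        ids: Sequence[str],
        measured: Sequence[float],
        estimated: Sequence[float],
    ) -> None:
        ids = tuple(str(i) for i in ids)
        measured_arr = np.asarray(measured, dtype=float)
        estimated_arr = np.asarray(estimated, dtype=float)
        if not (len(ids) == measured_arr.size == estimated_arr.size):
            raise ValidationError("ids, measured and estimated must have equal length")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate ids in paired cohort")
        if not (np.isfinite(measured_arr).all() and np.isfinite(estimated_arr).all()):
            raise ValidationError("paired cohort must not contain missing values")
        self.ids = ids
        self.measured = measured_arr
        self.estimated = estimated_arr

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PairedCohort(n={self.n})"
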