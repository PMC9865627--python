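"""Step-test protocol logic.

The step test is three 1-min stepping stages (15, 20, 25 steps/min on a
30 cm step) followed by two 1-min seated recovery stages.  Its summary
statistic, the HR index, adds the HR rise during exercise to the HR drop
during recovery::

    HR index = (HR at exercise stage 3 - HR at exercise stage 1)
             + (HR at recovery stage 1 - HR at recovery stage 2)

Fit subjects reach a lower exercise HR and have little elevation left to
shed during recovery, so lower index values indicate higher fitness.  The
module also houses the two age-predicted maximal-HR
formulas, the stage-3 skip rule, and the maximal-effort attainment check
applied to the criterion treadmill test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .types import StepTestRecord, TreadmillRecord, ValidationError

__all__ = [
    "MaxHrFormula",
    "EffortCriteria",
    "HrIndexUndefined",
    "compute_hr_index",
    "predicted_max_hr",
    "check_stage3_skip",
    "verify_max_effort",
    "vo2_plateau_reached",
]


class MaxHrFormula(str, Enum):
    """Age-predicted maximal heart rate formulas.

    ``FOX`` (220 - age) is used by the skip rule and the maximal-effort
    check; ``TANAKA`` (208 - 0.7*age) is used for the extrapolation target
    of the line-fit estimator.  The two agree only at age 40 (180 bpm).
    """

    FOX = "fox_220_minus_age"
    TANAKA = "tanaka_208_minus_0p7_age"


class HrIndexUndefined(ValidationError):
    """HR index cannot be computed (stage 3 skipped)."""


#: Reason string attached to regression estimates blocked by a skipped stage 3.
HR_INDEX_SKIP_REASON = "hr_index undefined when stage 3 skipped"


def compute_hr_index(record: StepTestRecord) -> float:
    """HR index in bpm; may be negative (recovery term can dominate).

    Raises :class:`HrIndexUndefined` when stage 3 was skipped: the index is
    defined on the full protocol only.
    """
    if record.stage3_skipped or record.hr_ex3 is None:
        raise HrIndexUndefined(HR_INDEX_SKIP_REASON)
    return (record.hr_ex3 - record.hr_ex1) + (record.hr_rec1 - record.hr_rec2)


def predicted_max_hr(age: float, formula: MaxHrFormula = MaxHrFormula.TANAKA) -> float:
    """Age-predicted maximal HR in bpm under the chosen formula."""
    if age <= 0:
        raise ValidationError(f"age must be positive, got {age}")
    if formula is MaxHrFormula.FOX:
        return 220.0 - age
    return 208.0 - 0.7 * age


def check_stage3_skip(
    hr_end_stage2: float,
    rpe_end_stage2: Optional[float],
    age: float,
) -> bool:
    """Whether the protocol permits skipping stage 3.

    Both criteria must hold at the end of stage 2: HR at or above 80% of the
    Fox age-predicted maximum (220 - age), and a Borg RPE at or above 17.
    The thresholds are protocol targets, hence read as >=.  A missing RPE
    cannot establish the second criterion: the result is False with a warning.
    """
    if rpe_end_stage2 is None:
        warnings.warn(
            "stage-3 skip rule: RPE at end of stage 2 missing; "
            "criterion cannot be established, not skipping",
            UserWarning,
            stacklevel=2,
        )
        return False
    hr_target = 0.8 * predicted_max_hr(age, MaxHrFormula.FOX)
    return hr_end_stage2 >= hr_target and rpe_end_stage2 >= 17.0


@dataclass(frozen=True)
class EffortCriteria:
    """Thresholds for accepting a treadmill peak VO2 as a true maximum.

    The RER and RPE thresholds are strict ("exceeded"), asymmetric with the
    skip rule's inclusive targets; the HR criterion is a ±10 bpm window
    around the Fox age-predicted maximum.  At least ``min_criteria_met`` of
    the four criteria must hold.
    """

    rer_threshold: float = 1.10
    hr_window: float = 10.0
    rpe_threshold: float = 17.0
    min_criteria_met: int = 3

    def __post_init__(self) -> None:
        if min(self.rer_threshold, self.hr_window, self.rpe_threshold) <= 0:
            raise ValidationError("effort thresholds must be positive")
        if not 1 <= self.min_criteria_met <= 4:
            raise ValidationError("min_criteria_met must be in [1, 4]")


def verify_max_effort(
    t: TreadmillRecord,
    age: float,
    criteria: EffortCriteria = EffortCriteria(),
) -> tuple[bool, dict[str, bool]]:
    """Check maximal-effort attainment; returns (verdict, per-criterion flags).

    An unknown plateau (``None``) counts as unmet.
    """
    breakdown = {
        "rer": t.rer_max > criteria.rer_threshold,
        "hr": abs(t.hr_max_observed - predicted_max_hr(age, MaxHrFormula.FOX))
        <= criteria.hr_window,
        "rpe": t.rpe_max > criteria.rpe_threshold,
        "plateau": bool(t.plateau),
    }
    return sum(breakdown.values()) >= criteria.min_criteria_met, breakdown


def vo2_plateau_reached(
    vo2_penultimate: float,
    vo2_final: float,
    delta_threshold: float = 2.0,
) -> bool:
    """Plateau helper: final-stage VO2 rise below ``delta_threshold``.

    Provided for convenience only and never invoked automatically: the
    plateau flag on :class:`~stepvo2.types.TreadmillRecord` is an input,
    since plateau operationalizations vary across laboratories.
    """
    return (vo2_final - vo2_penultimate) < delta_threshold
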