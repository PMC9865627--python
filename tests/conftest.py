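import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stepvo2 import Participant, Sex, StepTestRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def participant_f():
    """Female participant at the published per-sex mean predictors."""
    return Participant(id="F-mean", age=48.3, sex=Sex.FEMALE, pa_score=8.6, bmi=21.6)


@pytest.fixture
def participant_m():
    """Male participant at the published per-sex mean predictors."""
    return Participant(id="M-mean", age=48.3, sex=Sex.MALE, pa_score=11.9, bmi=24.6)


def record_on_line(intercept, slope, stage_vo2, noise=None):
    """Step record with HR = intercept + slope*x at each stage constant."""
    hr = {name: intercept + slope * x for name, x in stage_vo2.items()}
    if noise:
        for name, eps in noise.items():
            hr[name] += eps
    return StepTestRecord(
        hr_rest=hr["rest"],
        hr_ex1=hr["ex1"],
        hr_ex2=hr["ex2"],
        hr_ex3=hr["ex3"],
        hr_rec1=hr["rec1"],
        hr_rec2=hr["rec2"],
    )


@pytest.fixture
def make_line_record():
    return record_on_line


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
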