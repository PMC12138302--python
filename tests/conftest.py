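import numpy as np
import pandas as pd
import pytest

from stepimpact.preprocessing import AnalysisWindow, StepSeries
from stepimpact.synthetic import (
    DemographyParams,
    EffectScenario,
    generate_profiles,
    generate_step_logs,
    generate_weather,
)


@pytest.fixture(scope="session")
def window28() -> AnalysisWindow:
    return AnalysisWindow(post_end=28)


def make_series(steps_by_offset: dict, user_id="u0", post_end=28,
                registration="2021-05-10") -> StepSeries:
    """Build a StepSeries from {offset: value}; unmentioned offsets missing."""
    offsets = np.arange(-35, post_end + 1)
    steps = np.full(offsets.shape, np.nan)
    for off, val in steps_by_offset.items():
        steps[off + 35] = val
    return StepSeries(
        user_id=user_id,
        registration_date=pd.Timestamp(registration),
        offsets=offsets,
        steps=steps,
        imputed=np.zeros(offsets.shape, dtype=bool),
    )


@pytest.fixture(scope="session")
def quiet_scenario() -> EffectScenario:
    """All variation disabled: constant 5000 steps/day, no effect."""
    return EffectScenario(
        true_effect=0.0,
        weekend_offset=0.0,
        weather_coefficients={},
        baseline_mean=5000.0,
        baseline_sd=0.0,
        noise_sd=0.0,
        stream_disagreement_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve clean users with a known 400 steps/day effect."""
    demo = DemographyParams()
    users = generate_profiles(12, demo, seed=5)
    lo = users["registration_date"].min() - pd.Timedelta(days=36)
    hi = users["registration_date"].max() + pd.Timedelta(days=29)
    weather = generate_weather(lo.date(), (hi - lo).days + 1, seed=6)
    scenario = EffectScenario(true_effect=400.0, noise_sd=600.0, seed=7)
    steps = generate_step_logs(users, weather, scenario)
    return steps, users, weather, scenario
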