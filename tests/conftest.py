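import warnings

import pytest

from homepatterns import features as ft
from homepatterns.simulate import SimulationSpec, simulate_cohorts


@pytest.fixture(scope="session")
def default_cohort():
    """5 OP + 5 CI participants, 55 days, default profiles."""
    spec = SimulationSpec(n_op=5, n_ci=5, n_days=55, seed=7)
    streams, labels = simulate_cohorts(spec)
    return streams, dict(zip(labels["user_id"], labels["cohort"]))


@pytest.fixture(scope="session")
def default_day_frames(default_cohort):
    streams, _ = default_cohort
    return {s.user_id: ft.day_feature_frame(s) for s in streams}


@pytest.fixture(scope="session")
def sweep_cohort():
    """Cohort long enough for the 78/57/36/22-day dataset-size sweep."""
    spec = SimulationSpec(n_op=5, n_ci=5, n_days=78, seed=11)
    streams, labels = simulate_cohorts(spec)
    frames = {s.user_id: ft.day_feature_frame(s) for s in streams}
    return frames, dict(zip(labels["user_id"], labels["cohort"]))


@pytest.fixture(autouse=True)
def _quiet_constant_column_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="dropping .* constant")
        yield
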