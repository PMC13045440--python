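"""Shared fixtures: schedules, diets and small synthetic cohorts.

Cohort fixtures are module-scoped because generation is the slow part;
all tests treat them as read-only.
"""

import pandas as pd
import pytest

from mealscan.config import DietSpec, GeneratorConfig, LightSchedule
from mealscan.segmentation import segment
from mealscan.simulate import generate_feeding_events


@pytest.fixture(scope="session")
def schedule():
    return LightSchedule()


@pytest.fixture(scope="session")
def diet():
    return DietSpec()


def make_events(rows, animal="M01"):
    """Event frame from (start_min, end_min, grams) tuples on day 0 (06:00)."""
    sched = LightSchedule()
    anchor = sched.day_anchor(0)
    return pd.DataFrame(
        {
            "animal_id": animal,
            "start": [anchor + pd.Timedelta(minutes=s) for s, _, _ in rows],
            "end": [anchor + pd.Timedelta(minutes=e) for _, e, _ in rows],
            "intake_g": [g for _, _, g in rows],
        }
    )


@pytest.fixture(scope="session")
def baseline_events(schedule):
    cfg = GeneratorConfig(seed=0, n_animals=7, state="baseline")
    return generate_feeding_events(cfg, days=3)


@pytest.fixture(scope="session")
def kpc_events(schedule):
    cfg = GeneratorConfig(seed=0, n_animals=7, state="kpc_d14")
    return generate_feeding_events(cfg, days=3, start_day=13, context_code=13)


@pytest.fixture(scope="session")
def paired_meals(baseline_events, kpc_events, diet, schedule):
    evb = baseline_events.copy()
    evb["phase"] = "baseline"
    evk = kpc_events.copy()
    evk["phase"] = "kpc_d14"
    return segment(pd.concat([evb, evk], ignore_index=True), diet, schedule)
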