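import numpy as np
import pandas as pd
import pytest

from metdiary import (
    default_compendium,
    default_config,
    generate_cohort,
    score_cohort,
)
from metdiary.diary import DiaryDay, N_SLOTS, ParticipantRecord


@pytest.fixture(scope="session")
def comp():
    return default_compendium()


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged study-scale cohort (n=2046, packaged seed)."""
    return generate_cohort(default_config())


@pytest.fixture(scope="session")
def default_table(default_cohort, comp):
    return score_cohort(default_cohort, comp)


@pytest.fixture(scope="session")
def small_table(comp):
    """A 400-person cohort for the cheaper statistical tests."""
    cfg = default_config().model_copy(update={"n_total": 400, "seed": 777})
    return score_cohort(generate_cohort(cfg), comp)


def uniform_day(code: str, day_type: str = "weekday") -> DiaryDay:
    return DiaryDay(day_type=day_type, slots=[code] * N_SLOTS)


def day_from_counts(counts: list[tuple[str, int]], day_type: str = "weekday") -> DiaryDay:
    slots = []
    for code, k in counts:
        slots.extend([code] * k)
    assert len(slots) == N_SLOTS
    return DiaryDay(day_type=day_type, slots=slots)


def make_record(
    weekday: DiaryDay,
    weekend: DiaryDay,
    pid: str = "P1",
    **overrides,
) -> ParticipantRecord:
    fields = dict(
        participant_id=pid,
        sex="man",
        age=40,
        area="urban",
        occupation="employee",
        income_band="5-7",
        marital_status="married",
        exercise_habit="none",
        weight=65.0,
        bmi=22.0,
        weekday_diary=weekday,
        weekend_diary=weekend,
    )
    fields.update(overrides)
    return ParticipantRecord(**fields)


def random_complete_day(rng: np.random.Generator, comp, day_type: str = "weekday") -> DiaryDay:
    codes = rng.choice(comp.codes, size=N_SLOTS)
    return DiaryDay(day_type=day_type, slots=list(codes))
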