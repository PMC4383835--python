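"""Two-day 15-minute activity diaries and participant covariates.

A diary day is 96 consecutive 15-minute slots (slot ``i`` covers
``[15*i, 15*(i+1))`` minutes after 00:00). Every participant contributes one
weekday and one weekend day; a participant is *complete* only when all
192 slots are filled, and incomplete participants are excluded before
scoring — no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from .compendium import Compendium

N_SLOTS = 96
SLOT_MINUTES = 15
DAY_TYPES = ("weekday", "weekend")
SEXES = ("man", "woman")
AREAS = ("urban", "urban_rural", "rural")
OCCUPATIONS = (
    "employee",
    "self_employed",
    "housewife_fulltime",
    "housewife_parttime",
    "student",
    "unemployed",
    "other",
)
INCOME_BANDS = ("<3", "3-5", "5-7", "7-10", ">10")  # million yen / year
MARITAL_STATUSES = ("married", "unmarried")
EXERCISE_HABITS = ("none", "twice_weekly_30min")

MISSING: Optional[str] = None


class DiaryFormatError(ValueError):
    """Raised for malformed diary/covariate input files."""


@dataclass
class DiaryDay:
    """One recorded day: 96 activity codes, ``None`` marking a missing slot."""

    day_type: str
    slots: list[Optional[str]]

    def __post_init__(self) -> None:
        if self.day_type not in DAY_TYPES:
            raise DiaryFormatError(f"day_type must be one of {DAY_TYPES}, got {self.day_type!r}")
        if len(self.slots) != N_SLOTS:
            raise DiaryFormatError(f"a diary day needs exactly {N_SLOTS} slots, got {len(self.slots)}")

    @classmethod
    def empty(cls, day_type: str) -> "DiaryDay":
        return cls(day_type=day_type, slots=[MISSING] * N_SLOTS)

    @property
    def n_missing(self) -> int:
        return sum(s is None for s in self.slots)

    def is_complete(self) -> bool:
        return self.n_missing == 0

    def validate_codes(self, compendium: Compendium) -> None:
        for i, code in enumerate(self.slots):
            if code is not None and code not in compendium:
                raise DiaryFormatError(f"slot {i}: unknown activity code {code!r}")


@dataclass
class ParticipantRecord:
    participant_id: str
    sex: str
    age: int
    area: str
    occupation: str
    income_band: str
    marital_status: str
    exercise_habit: str
    weight: float
    bmi: float
    weekday_diary: DiaryDay
    weekend_diary: DiaryDay

    def __post_init__(self) -> None:
        if self.weekday_diary.day_type != "weekday" or self.weekend_diary.day_type != "weekend":
            raise DiaryFormatError(
                f"participant {self.participant_id}: diaries carry the wrong day types"
            )

    def covariates(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "sex": self.sex,
            "age": self.age,
            "area": self.area,
            "occupation": self.occupation,
            "income_band": self.income_band,
            "marital_status": self.marital_status,
            "exercise_habit": self.exercise_habit,
            "weight": self.weight,
            "bmi": self.bmi,
        }


def is_complete(record: ParticipantRecord) -> bool:
    """True iff all 96 slots of BOTH diaries are filled."""
    return record.weekday_diary.is_complete() and record.weekend_diary.is_complete()


@dataclass
class Cohort:
    records: list[ParticipantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DiaryFormatError(f"duplicate participant ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)


@dataclass
class ExclusionReport:
    n_total: int
    n_retained: int
    n_excluded: int
    pct_excluded: float  # excluded / total * 100, rounded to 2 decimals


def filter_complete(cohort: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Drop participants without two full 24-hour diaries.

    Mirrors the analysis-set rule of diary surveys: a single unfilled slot
    invalidates the participant.
    """
    retained = [r for r in cohort.records if is_complete(r)]
    n_total = len(cohort.records)
    n_excluded = n_total - len(retained)
    pct = round(100.0 * n_excluded / n_total, 2) if n_total else 0.0
    report = ExclusionReport(
        n_total=n_total, n_retained=len(retained), n_excluded=n_excluded, pct_excluded=pct
    )
    return Cohort(records=retained, provenance=cohort.provenance), report


# ---------------------------------------------------------------------------
# I/O: long-format diary CSV + covariate CSV

DIARY_COLUMNS = ["participant_id", "day_type", "slot", "activity_code"]
COVARIATE_COLUMNS = [
    "participant_id", "sex", "age", "area", "occupation",
    "income_band", "marital_status", "exercise_habit", "weight", "bmi",
]


def read_diaries(
    diary_file: str | Path,
    covariate_file: str | Path,
    compendium: Compendium,
    provenance: str = "",
) -> Cohort:
    """Assemble a cohort from a long diary CSV and a covariate CSV.

    One diary row fills one slot; slots never mentioned stay missing.
    Diary rows whose id has no covariate row are a format error; covariate
    rows without diary rows yield fully missing diaries.
    """
    cov = pd.read_csv(covariate_file, dtype={"participant_id": str})
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing_cols:
        raise DiaryFormatError(f"covariate file missing columns: {missing_cols}")

    diary = pd.read_csv(
        diary_file, dtype={"participant_id": str, "activity_code": str}
    )
    missing_cols = [c for c in DIARY_COLUMNS if c not in diary.columns]
    if missing_cols:
        raise DiaryFormatError(f"diary file missing columns: {missing_cols}")

    bad_slots = diary[(diary["slot"] < 0) | (diary["slot"] >= N_SLOTS)]
    if len(bad_slots):
        raise DiaryFormatError(
            f"slot index outside 0-{N_SLOTS - 1}: first offender "
            f"{bad_slots.iloc[0]['participant_id']} slot {bad_slots.iloc[0]['slot']}"
        )
    bad_day = set(diary["day_type"]) - set(DAY_TYPES)
    if bad_day:
        raise DiaryFormatError(f"unknown day_type values: {sorted(bad_day)}")

    known_ids = set(cov["participant_id"])
    orphan = set(diary["participant_id"]) - known_ids
    if orphan:
        raise DiaryFormatError(f"diary rows without covariate row: {sorted(orphan)[:5]}")

    slots_by_key: dict[tuple[str, str], list[Optional[str]]] = {}
    for row in diary.itertuples():
        key = (row.participant_id, row.day_type)
        day = slots_by_key.setdefault(key, [MISSING] * N_SLOTS)
        day[int(row.slot)] = row.activity_code

    records = []
    for row in cov.itertuples():
        pid = row.participant_id
        wd = DiaryDay("weekday", slots_by_key.get((pid, "weekday"), [MISSING] * N_SLOTS))
        we = DiaryDay("weekend", slots_by_key.get((pid, "weekend"), [MISSING] * N_SLOTS))
        wd.validate_codes(compendium)
        we.validate_codes(compendium)
        records.append(
            ParticipantRecord(
                participant_id=pid,
                sex=row.sex,
                age=int(row.age),
                area=row.area,
                occupation=row.occupation,
                income_band=row.income_band,
                marital_status=row.marital_status,
                exercise_habit=row.exercise_habit,
                weight=float(row.weight),
                bmi=float(row.bmi),
                weekday_diary=wd,
                weekend_diary=we,
            )
        )
    return Cohort(records=records, provenance=provenance or str(diary_file))


def write_diaries(cohort: Cohort, diary_file: str | Path, covariate_file: str | Path) -> None:
    """Write a cohort back to the long diary CSV + covariate CSV dialects."""
    diary_rows = []
    cov_rows = []
    for rec in cohort:
        cov_rows.append(rec.covariates())
        for day in (rec.weekday_diary, rec.weekend_diary):
            for i, code in enumerate(day.slots):
                if code is not None:
                    diary_rows.append(
                        {
                            "participant_id": rec.participant_id,
                            "day_type": day.day_type,
                            "slot": i,
                            "activity_code": code,
                        }
                    )
    pd.DataFrame(diary_rows, columns=DIARY_COLUMNS).to_csv(diary_file, index=False)
    pd.DataFrame(cov_rows, columns=COVARIATE_COLUMNS).to_csv(covariate_file, index=False)
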