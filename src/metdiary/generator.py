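"""Seeded synthetic diary-cohort generator.

Emulates a 2046-person Japanese web-diary study population (adults 30–59,
three residence strata: urban / urban-rural / rural) by sampling stratified
covariates and building each person's two diary days out of contiguous
activity blocks — a midnight-wrapping sleep block, commute and work blocks
with an occupational intensity mix, household tasks, errand/outing trips,
optional sport sessions, and low-intensity leisure filler.

Calibration operates only at the schedule level (durations, mode
probabilities, intensity mixes); summary statistics are never drawn
directly, so the generator and the scorer form a genuine round-trip.
All randomness flows from one seed with a named substream per participant:
adding participants never perturbs earlier ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import importlib.resources
import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .compendium import Compendium, default_compendium
from .diary import AREAS, Cohort, DiaryDay, N_SLOTS, ParticipantRecord
from .scoring import score_cohort

logger = logging.getLogger(__name__)

SLOT_MIN = 15
COMMUTE_MODES = ("walk", "transit", "car", "cycle")
JOB_TYPES = ("office", "standing", "manual")
WORK_SEGMENTS = ("sitting", "standing", "vigorous", "walking")
AGE_BANDS = ("30-39", "40-49", "50-59")

# --- activity-code menus the schedule builder draws from -------------------
# (code, probability) per behavioural slot type; codes refer to the packaged
# compendium. Probabilities sum to 1.

SLEEP_CODE = "U01"
MEAL_CODE = "U02"
GROOM_CODE = "U03"
BATH_CODE = "U04"

WORK_SEGMENT_CODES = {
    "sitting": [("W01", 0.75), ("W02", 0.15), ("W03", 0.10)],
    "standing": [("W05", 0.20), ("W06", 0.50), ("W07", 0.15), ("W08", 0.05), ("W11", 0.05), ("W16", 0.05)],
    "vigorous": [("W12", 0.35), ("W13", 0.35), ("W14", 0.20), ("W15", 0.10)],
    "walking": [("W09", 0.85), ("W10", 0.15)],
}

COMMUTE_CODES = {"walk": "T01", "transit": "T03", "car": "T06", "cycle": "T09"}
TRANSIT_ACCESS_CODE = "T01"  # the walking legs of a transit commute

HOUSEHOLD_TASK_CODES = {
    "cooking": [("H01", 0.75), ("H02", 0.25)],
    "cleaning": [("H04", 0.15), ("H05", 0.60), ("H06", 0.25)],
    "laundry": [("H07", 1.0)],
    "shopping": [("H09", 0.7), ("H10", 0.3)],
    "childcare": [("H11", 0.20), ("H12", 0.55), ("H13", 0.25)],
    "gardening": [("H15", 1.0)],
    "carwash": [("H17", 1.0)],
}

SPORT_CODES = [
    ("L17", 0.30), ("L18", 0.10), ("L19", 0.08), ("L21", 0.04), ("L22", 0.05),
    ("L23", 0.04), ("L24", 0.03), ("L25", 0.03), ("L27", 0.03), ("L33", 0.10),
    ("L34", 0.07), ("L35", 0.08), ("L36", 0.02), ("L37", 0.02), ("L26", 0.02),
    ("L31", 0.02), ("L39", 0.03), ("L44", 0.01), ("L32", 0.03),
]

LEISURE_CODES = [
    ("L01", 0.30), ("L02", 0.22), ("L03", 0.05), ("L04", 0.10), ("L05", 0.03),
    ("L06", 0.03), ("L07", 0.08), ("L08", 0.05), ("L09", 0.02), ("L10", 0.03),
    ("L11", 0.05), ("L16", 0.04),
]


# --- configuration schema ---------------------------------------------------


class Normal(BaseModel):
    """Mean/SD of a truncated-normal duration draw (minutes)."""

    mean: float = Field(ge=0)
    sd: float = Field(ge=0)


class DayPair(BaseModel):
    """A probability that differs between day types."""

    weekday: float = Field(ge=0, le=1)
    weekend: float = Field(ge=0, le=1)


def _check_simplex(d: dict, what: str) -> dict:
    total = sum(d.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities sum to {total}, not 1")
    if any(v < 0 for v in d.values()):
        raise ValueError(f"{what} has a negative probability")
    return d


class SleepParams(BaseModel):
    weekday: Normal
    weekend: Normal


class WorkParams(BaseModel):
    works_prob: dict[str, DayPair]  # by occupation
    duration_mean: dict[str, float]  # weekday minutes, by occupation
    duration_sd: float = Field(ge=0)
    weekend_duration_factor: float = Field(ge=0, le=1)
    job_mix: dict[str, float]  # office / standing / manual

    @field_validator("job_mix")
    @classmethod
    def _job_mix_simplex(cls, v):
        if set(v) != set(JOB_TYPES):
            raise ValueError(f"job_mix needs keys {JOB_TYPES}")
        return _check_simplex(v, "job_mix")


class CommuteParams(BaseModel):
    mode_probs: dict[str, float]
    oneway_minutes: dict[str, Normal]  # walk, transit_ride, transit_access, car, cycle

    @field_validator("mode_probs")
    @classmethod
    def _modes_simplex(cls, v):
        if set(v) != set(COMMUTE_MODES):
            raise ValueError(f"mode_probs needs keys {COMMUTE_MODES}")
        return _check_simplex(v, "commute mode")


class TripParams(BaseModel):
    """Non-commute transport: errands on weekdays, outings on weekends."""

    prob: DayPair
    mode_probs: dict[str, float]
    minutes: Normal  # round trip, weekday
    weekend_minutes_factor: float = 1.0

    @field_validator("mode_probs")
    @classmethod
    def _modes_simplex(cls, v):
        return _check_simplex(v, "trip mode")


class HouseholdTask(BaseModel):
    prob: DayPair
    minutes: Normal


class SportParams(BaseModel):
    prob_habit: DayPair
    prob_no_habit: DayPair
    minutes_habit: Normal
    minutes_no_habit: Normal


class StratumParams(BaseModel):
    """Schedule parameters for one area × sex stratum."""

    sleep: SleepParams
    work: WorkParams
    commute: CommuteParams
    trip: TripParams
    household: dict[str, HouseholdTask]
    sport: SportParams


class GeneratorConfig(BaseModel):
    name: str = "default"
    n_total: int = Field(gt=0)
    seed: int
    incompleteness_prob: float = Field(ge=0, le=1, default=0.0)
    area_proportions: dict[str, float]
    sex_by_area: dict[str, dict[str, float]]
    age_bands_by_area: dict[str, dict[str, float]]
    occupation_probs_by_sex: dict[str, dict[str, float]]
    income_probs_by_area: dict[str, dict[str, float]]
    marriage_prob: float = Field(ge=0, le=1)
    exercise_habit_prob_by_area: dict[str, float]
    weight_by_sex: dict[str, Normal]
    bmi_by_sex: dict[str, Normal]
    job_compositions: dict[str, dict[str, float]]  # job type -> segment fractions
    schedule: dict[str, dict[str, StratumParams]]  # area -> sex -> params

    @field_validator("area_proportions")
    @classmethod
    def _areas(cls, v):
        if set(v) != set(AREAS):
            raise ValueError(f"area_proportions needs keys {AREAS}")
        return _check_simplex(v, "area")

    @model_validator(mode="after")
    def _nested_simplexes(self):
        for area, d in self.sex_by_area.items():
            _check_simplex(d, f"sex_by_area[{area}]")
        for area, d in self.age_bands_by_area.items():
            _check_simplex(d, f"age_bands_by_area[{area}]")
        for sex, d in self.occupation_probs_by_sex.items():
            _check_simplex(d, f"occupation_probs_by_sex[{sex}]")
        for area, d in self.income_probs_by_area.items():
            _check_simplex(d, f"income_probs_by_area[{area}]")
        for job, d in self.job_compositions.items():
            _check_simplex(d, f"job_compositions[{job}]")
        return self

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def default_config() -> GeneratorConfig:
    """The packaged calibrated configuration (n=2046, seed 20120712)."""
    ref = importlib.resources.files("metdiary.data") / "default_config.json"
    with importlib.resources.as_file(ref) as path:
        return GeneratorConfig.from_json(path)


def null_config(n_total: int = 300, seed: int = 0) -> GeneratorConfig:
    """A null-calibrated variant: every area stratum shares identical
    covariate distributions and schedule parameters (sexes may still
    differ), so area effects and sex×area interactions are exactly null.
    Useful for type-I-error calibration of the inference stage."""
    cfg = default_config()
    ref_area = "urban"
    third = {a: 1.0 / 3.0 for a in AREAS}
    upd = cfg.model_dump()
    upd.update(
        name="null",
        n_total=n_total,
        seed=seed,
        area_proportions=third,
        sex_by_area={a: cfg.sex_by_area[ref_area] for a in AREAS},
        age_bands_by_area={a: cfg.age_bands_by_area[ref_area] for a in AREAS},
        income_probs_by_area={a: cfg.income_probs_by_area[ref_area] for a in AREAS},
        exercise_habit_prob_by_area={a: cfg.exercise_habit_prob_by_area[ref_area] for a in AREAS},
        schedule={a: cfg.model_dump()["schedule"][ref_area] for a in AREAS},
    )
    return GeneratorConfig.model_validate(upd)


# --- schedule building ------------------------------------------------------


@dataclass
class PersonParams:
    """Per-person resolved draw: stratum parameters plus the person-level
    latent choices that persist across both diary days."""

    occupation: str
    job_type: str
    commute_mode: str
    exercise_habit: bool
    childcare_active: bool
    stratum: StratumParams
    compositions: dict[str, dict[str, float]]


def _draw_cat(rng: np.random.Generator, d: dict[str, float]) -> str:
    keys = list(d)
    p = np.array([d[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _draw_code(rng: np.random.Generator, menu: list[tuple[str, float]]) -> str:
    p = np.array([w for _, w in menu], dtype=float)
    return menu[int(rng.choice(len(menu), p=p / p.sum()))][0]


def _draw_slots(rng: np.random.Generator, spec: Normal, lo_min: float = 0.0,
                hi_min: float = 24 * 60.0) -> int:
    """Truncated-normal duration rounded to whole 15-minute slots."""
    x = rng.normal(spec.mean, spec.sd) if spec.sd > 0 else spec.mean
    x = min(max(x, lo_min), hi_min)
    return int(round(x / SLOT_MIN))


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer split of `total` proportional to `fractions`."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def build_schedule(person: PersonParams, day_type: str, rng: np.random.Generator) -> DiaryDay:
    """Assemble one complete 96-slot day for a resolved person.

    Blocks are laid out on a wake-to-bed timeline inside a
    midnight-wrapping sleep block; if requested blocks exceed the waking
    day, discretionary blocks (trip, sport, household) are truncated
    proportionally before work and commute are touched.
    """
    p = person.stratum
    sleep_spec = p.sleep.weekday if day_type == "weekday" else p.sleep.weekend
    sleep_slots = _draw_slots(rng, sleep_spec, lo_min=240, hi_min=24 * 60)
    sleep_slots = min(sleep_slots, N_SLOTS)
    awake = N_SLOTS - sleep_slots
    # portion of sleep before midnight (so waking time is contiguous)
    pre = int(rng.integers(2, 7)) if sleep_slots > 7 else 0
    pre = min(pre, sleep_slots)

    fixed: list[tuple[str, int]] = []
    work_blocks: list[tuple[str, int]] = []
    flex: list[tuple[str, int]] = []

    # morning routine + main meals
    fixed += [(GROOM_CODE, 2), (MEAL_CODE, 1)]  # grooming, breakfast
    fixed += [(MEAL_CODE, 2), (BATH_CODE, 1)]  # dinner, bath (placed at day end)

    wp = p.work.works_prob.get(person.occupation)
    works = False
    if wp is not None:
        prob = wp.weekday if day_type == "weekday" else wp.weekend
        works = rng.random() < prob
    if works:
        dur_mean = p.work.duration_mean[person.occupation]
        if day_type == "weekend":
            dur_mean *= p.work.weekend_duration_factor
        w_slots = _draw_slots(rng, Normal(mean=dur_mean, sd=p.work.duration_sd), lo_min=60)
        comp = person.compositions[person.job_type]
        fracs = np.array([comp[s] for s in WORK_SEGMENTS], dtype=float)
        seg_slots = _largest_remainder(w_slots, fracs / fracs.sum())
        half = []
        for seg, k in zip(WORK_SEGMENTS, seg_slots):
            if k > 0:
                half.append((_draw_code(rng, WORK_SEGMENT_CODES[seg]), int(k)))
        # commute legs
        mode = person.commute_mode
        legs: list[tuple[str, int]] = []
        if mode == "transit":
            ride = _draw_slots(rng, p.commute.oneway_minutes["transit_ride"])
            # a transit commute always involves at least one walking slot
            access = max(1, _draw_slots(rng, p.commute.oneway_minutes["transit_access"]))
            legs = [(TRANSIT_ACCESS_CODE, access), (COMMUTE_CODES["transit"], ride)]
        else:
            ow = _draw_slots(rng, p.commute.oneway_minutes[mode])
            legs = [(COMMUTE_CODES[mode], ow)]
        legs = [(c, k) for c, k in legs if k > 0]
        work_blocks = legs + half[: len(half) // 2 + 1] + [(MEAL_CODE, 2)] \
            + half[len(half) // 2 + 1:] + [(c, k) for c, k in reversed(legs)]

    # non-commute trip (errand / outing)
    tp = p.trip
    t_prob = tp.prob.weekday if day_type == "weekday" else tp.prob.weekend
    if rng.random() < t_prob:
        minutes = Normal(
            mean=tp.minutes.mean * (tp.weekend_minutes_factor if day_type == "weekend" else 1.0),
            sd=tp.minutes.sd,
        )
        k = _draw_slots(rng, minutes)
        if k > 0:
            mode = _draw_cat(rng, tp.mode_probs)
            flex.append((COMMUTE_CODES[mode], k))

    # household tasks
    for task, hp in p.household.items():
        prob = hp.prob.weekday if day_type == "weekday" else hp.prob.weekend
        if task == "childcare" and not person.childcare_active:
            continue
        if rng.random() < prob:
            k = _draw_slots(rng, hp.minutes)
            if k > 0:
                flex.append((_draw_code(rng, HOUSEHOLD_TASK_CODES[task]), k))

    # sport session
    sp = p.sport
    s_prob = (sp.prob_habit if person.exercise_habit else sp.prob_no_habit)
    s_prob = s_prob.weekday if day_type == "weekday" else s_prob.weekend
    if rng.random() < s_prob:
        spec = sp.minutes_habit if person.exercise_habit else sp.minutes_no_habit
        k = _draw_slots(rng, spec)
        if k > 0:
            flex.append((_draw_code(rng, SPORT_CODES), k))

    # fit everything into the waking day
    def total(blocks):
        return sum(k for _, k in blocks)

    need = total(fixed) + total(work_blocks) + total(flex)
    if need > awake:
        overflow = need - awake
        logger.debug("schedule overflow of %d slots; truncating", overflow)
        flex_total = total(flex)
        cut = min(overflow, flex_total)
        if flex_total > 0 and cut > 0:
            keep = _largest_remainder(flex_total - cut,
                                      np.array([k for _, k in flex]) / flex_total)
            flex = [(c, int(k)) for (c, _), k in zip(flex, keep) if k > 0]
            overflow -= cut
        if overflow > 0 and work_blocks:
            wtot = total(work_blocks)
            cut = min(overflow, wtot)
            keep = _largest_remainder(wtot - cut,
                                      np.array([k for _, k in work_blocks]) / wtot)
            work_blocks = [(c, int(k)) for (c, _), k in zip(work_blocks, keep) if k > 0]
            overflow -= cut
        if overflow > 0:
            ftot = total(fixed)
            cut = min(overflow, ftot)
            keep = _largest_remainder(ftot - cut,
                                      np.array([k for _, k in fixed]) / max(ftot, 1))
            fixed = [(c, int(k)) for (c, _), k in zip(fixed, keep) if k > 0]
            overflow -= cut

    # leisure filler for the remaining slots, in 30–90-minute chunks
    leftover = awake - (total(fixed) + total(work_blocks) + total(flex))
    leisure: list[tuple[str, int]] = []
    while leftover > 0:
        k = int(min(leftover, rng.integers(2, 7)))
        leisure.append((_draw_code(rng, LEISURE_CODES), k))
        leftover -= k

    # timeline: morning, work bundle, trip/household/sport, leisure, dinner+bath
    morning, evening = fixed[:2], fixed[2:]
    n_lei = len(leisure)
    timeline = (
        morning + work_blocks + flex + leisure[: n_lei // 2] + evening[:1]
        + leisure[n_lei // 2:] + evening[1:]
    )

    slots: list[Optional[str]] = [None] * N_SLOTS
    wake = sleep_slots - pre
    for i in range(N_SLOTS - pre, N_SLOTS):
        slots[i] = SLEEP_CODE
    for i in range(0, wake):
        slots[i] = SLEEP_CODE
    pos = wake
    for code, k in timeline:
        for _ in range(k):
            if pos >= N_SLOTS - pre:
                break
            slots[pos] = code
            pos += 1
    while pos < N_SLOTS - pre:  # rounding guard: pad with leisure
        slots[pos] = LEISURE_CODES[0][0]
        pos += 1
    return DiaryDay(day_type=day_type, slots=slots)


def _age_from_band(rng: np.random.Generator, band: str) -> int:
    lo, hi = band.split("-")
    return int(rng.integers(int(lo), int(hi) + 1))


def sample_participant(
    config: GeneratorConfig, rng: np.random.Generator, participant_id: str
) -> ParticipantRecord:
    """Draw one participant: stratified covariates plus two built diaries."""
    area = _draw_cat(rng, config.area_proportions)
    sex = _draw_cat(rng, config.sex_by_area[area])
    band = _draw_cat(rng, config.age_bands_by_area[area])
    age = _age_from_band(rng, band)
    occupation = _draw_cat(rng, config.occupation_probs_by_sex[sex])
    income = _draw_cat(rng, config.income_probs_by_area[area])
    married = rng.random() < config.marriage_prob
    habit = rng.random() < config.exercise_habit_prob_by_area[area]
    w = config.weight_by_sex[sex]
    weight = float(np.clip(rng.normal(w.mean, w.sd), 35, 130))
    b = config.bmi_by_sex[sex]
    bmi = float(np.clip(rng.normal(b.mean, b.sd), 14, 45))

    stratum = config.schedule[area][sex]
    job_type = _draw_cat(rng, stratum.work.job_mix)
    commute_mode = _draw_cat(rng, stratum.commute.mode_probs)
    childcare_active = married or (rng.random() < 0.15)

    person = PersonParams(
        occupation=occupation,
        job_type=job_type,
        commute_mode=commute_mode,
        exercise_habit=habit,
        childcare_active=childcare_active,
        stratum=stratum,
        compositions=config.job_compositions,
    )
    weekday = build_schedule(person, "weekday", rng)
    weekend = build_schedule(person, "weekend", rng)
    return ParticipantRecord(
        participant_id=participant_id,
        sex=sex,
        age=age,
        area=area,
        occupation=occupation,
        income_band=income,
        marital_status="married" if married else "unmarried",
        exercise_habit="twice_weekly_30min" if habit else "none",
        weight=round(weight, 1),
        bmi=round(bmi, 1),
        weekday_diary=weekday,
        weekend_diary=weekend,
    )


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate ``config.n_total`` participants, reproducibly from the seed.

    A Bernoulli(``incompleteness_prob``) subset gets randomly masked slots,
    so downstream completeness filtering is exercised realistically.
    """
    if config.n_total <= 0:
        raise ValueError("n_total must be positive")
    records = []
    width = len(str(config.n_total))
    for i in range(config.n_total):
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, i])
        rec = sample_participant(config, rng, f"P{i:0{width}d}")
        if config.incompleteness_prob > 0 and rng.random() < config.incompleteness_prob:
            _mask_slots(rec, rng)
        records.append(rec)
    return Cohort(records=records, provenance=f"synthetic:{config.name}:seed={config.seed}")


def _mask_slots(rec: ParticipantRecord, rng: np.random.Generator) -> None:
    """Blank 1–96 random slots in one (or both) diaries."""
    targets = [rec.weekday_diary, rec.weekend_diary]
    which = rng.random()
    days = targets if which < 0.3 else [targets[int(which * 10) % 2]]
    for day in days:
        k = int(rng.integers(1, N_SLOTS + 1))
        for idx in rng.choice(N_SLOTS, size=k, replace=False):
            day.slots[int(idx)] = None


# --- calibration report -----------------------------------------------------

#: population marginals the default configuration is calibrated against
#: (value, absolute tolerance). Units: MET for mean_met, MET-hours/day for
#: the energy totals, minutes/day for times.
CALIBRATION_TARGETS = {
    "mean_met": (1.60, 0.05),
    "mvpa_median": (7.92, 1.0),
    "met_hours_urban": (37.9, 1.0),
    "met_hours_urban_rural": (38.8, 1.0),
    "met_hours_rural": (39.1, 1.0),
    "mvpa_rural_men": (10.8, 1.5),
    "commute_walk_min_urban": (24.6, 8.0),
    "commute_walk_min_rural": (7.4, 5.0),
    "transport_met_hours_urban": (4.1, 1.0),
    "work_min_overall": (262.0, 50.0),
}

CALIBRATION_ORDERINGS = (
    ("met_hours", "ascending"),  # urban < urban-rural < rural
    ("cat_met_hours_transportation", "urban_highest"),
)


@dataclass
class CalibrationRow:
    name: str
    target: float
    observed: float
    abs_dev: float
    tolerance: float
    ok: bool


@dataclass
class CalibrationReport:
    rows: list[CalibrationRow]
    orderings: dict[str, bool]
    n: int

    @property
    def all_ok(self) -> bool:
        return all(r.ok for r in self.rows) and all(self.orderings.values())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rows])


def calibration_report(
    config: GeneratorConfig, compendium: Compendium | None = None
) -> CalibrationReport:
    """Generate a seeded cohort, score it, and tabulate generated-vs-target
    marginals with absolute deviations."""
    comp = compendium or default_compendium()
    cohort = generate_cohort(config.model_copy(update={"incompleteness_prob": 0.0}))
    table = score_cohort(cohort, comp)
    by_area = table.groupby("area")

    obs = {
        "mean_met": table["mean_met"].mean(),
        "mvpa_median": table["mvpa_met_hours"].median(),
        "met_hours_urban": by_area["met_hours"].mean().get("urban", np.nan),
        "met_hours_urban_rural": by_area["met_hours"].mean().get("urban_rural", np.nan),
        "met_hours_rural": by_area["met_hours"].mean().get("rural", np.nan),
        "mvpa_rural_men": table.query("area == 'rural' and sex == 'man'")[
            "mvpa_met_hours"
        ].mean(),
        "commute_walk_min_urban": by_area["sub_minutes_commute_walk"].mean().get("urban", np.nan),
        "commute_walk_min_rural": by_area["sub_minutes_commute_walk"].mean().get("rural", np.nan),
        "transport_met_hours_urban": by_area["cat_met_hours_transportation"].mean().get("urban", np.nan),
        "work_min_overall": table["cat_minutes_work"].mean(),
    }
    rows = []
    for name, (target, tol) in CALIBRATION_TARGETS.items():
        o = float(obs[name])
        dev = abs(o - target)
        rows.append(CalibrationRow(name, target, o, dev, tol, bool(dev <= tol)))

    mh = by_area["met_hours"].mean()
    tr = by_area["cat_met_hours_transportation"].mean()
    orderings = {
        "total_met_hours_urban<urban_rural<rural": bool(
            mh.get("urban", np.inf) < mh.get("urban_rural", -np.inf) < mh.get("rural", -np.inf)
        ),
        "transport_met_hours_urban_highest": bool(
            "urban" in tr and tr["urban"] > tr.drop("urban").max()
        ),
    }
    return CalibrationReport(rows=rows, orderings=orderings, n=len(table))
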