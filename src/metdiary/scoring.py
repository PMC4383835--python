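"""MET scoring of diary days and weekday/weekend-weighted weekly metrics.

A day's mean MET is the average intensity over its 96 slots; MET-hours/day
is intensity × time (one slot at MET m contributes 0.25·m MET-hours).
Moderate-to-vigorous physical activity (MVPA) accumulates the full MET value
of every slot at or above 3.0 MET. The weekly figure for any metric combines
the two recorded days as (5·weekday + 2·weekend)/7, standing in for a
typical day of a 5+2 week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compendium import CATEGORIES, Compendium
from .diary import Cohort, DiaryDay, ParticipantRecord, SLOT_MINUTES

MVPA_THRESHOLD_MET = 3.0  # inclusive
WEEKDAY_WEIGHT, WEEKEND_WEIGHT = 5.0, 2.0
SLOT_HOURS = SLOT_MINUTES / 60.0


class ScoringError(ValueError):
    """Raised when scoring an incomplete or unresolvable diary."""


@dataclass
class DailyMetrics:
    mean_met: float
    met_hours: float
    mvpa_met_hours: float
    category_met_hours: dict[str, float]
    category_minutes: dict[str, float]
    subcategory_met_hours: dict[str, float]
    subcategory_minutes: dict[str, float]


def weekly_weight(weekday_value: float, weekend_value: float) -> float:
    """(5·weekday + 2·weekend) / 7."""
    return (WEEKDAY_WEIGHT * weekday_value + WEEKEND_WEIGHT * weekend_value) / 7.0


def score_day(day: DiaryDay, compendium: Compendium) -> DailyMetrics:
    """Score one complete 96-slot day against the compendium."""
    if not day.is_complete():
        raise ScoringError(f"cannot score an incomplete day ({day.n_missing} missing slots)")
    acts = [compendium.lookup(code) for code in day.slots]
    mets = np.array([a.met for a in acts])
    mean_met = float(mets.mean())
    met_hours = float(mets.sum() * SLOT_HOURS)
    mvpa = float(mets[mets >= MVPA_THRESHOLD_MET].sum() * SLOT_HOURS)

    cat_mh = {c: 0.0 for c in CATEGORIES}
    cat_min = {c: 0.0 for c in CATEGORIES}
    sub_mh: dict[str, float] = {}
    sub_min: dict[str, float] = {}
    for a in acts:
        cat_mh[a.category] += a.met * SLOT_HOURS
        cat_min[a.category] += SLOT_MINUTES
        sub_mh[a.subcategory] = sub_mh.get(a.subcategory, 0.0) + a.met * SLOT_HOURS
        sub_min[a.subcategory] = sub_min.get(a.subcategory, 0.0) + SLOT_MINUTES
    return DailyMetrics(
        mean_met=mean_met,
        met_hours=met_hours,
        mvpa_met_hours=mvpa,
        category_met_hours=cat_mh,
        category_minutes=cat_min,
        subcategory_met_hours=sub_mh,
        subcategory_minutes=sub_min,
    )


@dataclass
class WeeklyMetrics:
    participant_id: str
    covariates: dict
    mean_met: float
    met_hours: float
    mvpa_met_hours: float
    category_met_hours: dict[str, float]
    category_minutes: dict[str, float]
    subcategory_met_hours: dict[str, float]
    subcategory_minutes: dict[str, float]


def _weight_maps(wd: dict[str, float], we: dict[str, float]) -> dict[str, float]:
    keys = set(wd) | set(we)
    return {k: weekly_weight(wd.get(k, 0.0), we.get(k, 0.0)) for k in sorted(keys)}


def score_participant(record: ParticipantRecord, compendium: Compendium) -> WeeklyMetrics:
    """Weekly-weighted metrics for one participant with two complete diaries."""
    wd = score_day(record.weekday_diary, compendium)
    we = score_day(record.weekend_diary, compendium)
    return WeeklyMetrics(
        participant_id=record.participant_id,
        covariates=record.covariates(),
        mean_met=weekly_weight(wd.mean_met, we.mean_met),
        met_hours=weekly_weight(wd.met_hours, we.met_hours),
        mvpa_met_hours=weekly_weight(wd.mvpa_met_hours, we.mvpa_met_hours),
        category_met_hours=_weight_maps(wd.category_met_hours, we.category_met_hours),
        category_minutes=_weight_maps(wd.category_minutes, we.category_minutes),
        subcategory_met_hours=_weight_maps(wd.subcategory_met_hours, we.subcategory_met_hours),
        subcategory_minutes=_weight_maps(wd.subcategory_minutes, we.subcategory_minutes),
    )


#: column order of the scored cohort table, before category/subcategory blocks
CORE_COLUMNS = [
    "participant_id", "sex", "age", "area", "occupation", "income_band",
    "marital_status", "exercise_habit", "weight", "bmi",
    "mean_met", "met_hours", "mvpa_met_hours",
]


def score_cohort(cohort: Cohort, compendium: Compendium) -> pd.DataFrame:
    """One row of weekly metrics per participant, input order preserved.

    Column layout: covariates, the three headline metrics, then
    ``cat_met_hours_*``, ``cat_minutes_*`` for the five categories and
    ``sub_met_hours_*``, ``sub_minutes_*`` for every subcategory in the
    compendium (zero where a participant never logged it).

    Raises :class:`ScoringError` listing the ids of incomplete records.
    """
    incomplete = [
        r.participant_id
        for r in cohort
        if not (r.weekday_diary.is_complete() and r.weekend_diary.is_complete())
    ]
    if incomplete:
        raise ScoringError(
            f"{len(incomplete)} incomplete record(s); filter the cohort first. "
            f"Offending ids: {incomplete[:10]}"
        )

    # vectorised path: map codes -> (met, category idx, subcategory idx) once
    code_index = {c: i for i, c in enumerate(compendium.codes)}
    met_by_code = np.array([compendium.lookup(c).met for c in compendium.codes])
    cats = list(CATEGORIES)
    cat_of_code = np.array(
        [cats.index(compendium.lookup(c).category) for c in compendium.codes]
    )
    subs = sorted(compendium.subcategories())
    sub_of_code = np.array(
        [subs.index(compendium.lookup(c).subcategory) for c in compendium.codes]
    )
    n_codes = len(code_index)

    w = np.array([WEEKDAY_WEIGHT, WEEKEND_WEIGHT]) / 7.0
    rows = []
    for rec in cohort:
        idx = np.array(
            [[code_index[c] for c in rec.weekday_diary.slots],
             [code_index[c] for c in rec.weekend_diary.slots]]
        )  # (2, 96)
        mets = met_by_code[idx]
        mean_met = float(w @ mets.mean(axis=1))
        met_hours = float(w @ (mets.sum(axis=1) * SLOT_HOURS))
        mvpa = float(w @ (np.where(mets >= MVPA_THRESHOLD_MET, mets, 0.0).sum(axis=1) * SLOT_HOURS))

        # weighted per-code occupancy (slots), then fold into categories/subcats
        counts = np.zeros(n_codes)
        for d in (0, 1):
            counts += w[d] * np.bincount(idx[d], minlength=n_codes)
        code_minutes = counts * SLOT_MINUTES
        code_met_hours = counts * SLOT_HOURS * met_by_code

        row = dict(rec.covariates())
        row.update(mean_met=mean_met, met_hours=met_hours, mvpa_met_hours=mvpa)
        for ci, cat in enumerate(cats):
            mask = cat_of_code == ci
            row[f"cat_met_hours_{cat}"] = float(code_met_hours[mask].sum())
            row[f"cat_minutes_{cat}"] = float(code_minutes[mask].sum())
        for si, sub in enumerate(subs):
            mask = sub_of_code == si
            row[f"sub_met_hours_{sub}"] = float(code_met_hours[mask].sum())
            row[f"sub_minutes_{sub}"] = float(code_minutes[mask].sum())
        rows.append(row)

    columns = (
        CORE_COLUMNS
        + [f"cat_met_hours_{c}" for c in cats]
        + [f"cat_minutes_{c}" for c in cats]
        + [f"sub_met_hours_{s}" for s in subs]
        + [f"sub_minutes_{s}" for s in subs]
    )
    return pd.DataFrame(rows, columns=columns)


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    hist_counts: list[int]
    hist_edges: list[float]
    sd_defined: bool = True


def distribution_summary(table: pd.DataFrame, metric: str, bins: int | list = 20) -> SummaryStats:
    """Mean/SD (n−1), median and IQR (linear-interpolation percentiles),
    plus histogram counts for distribution plots."""
    if len(table) == 0:
        raise ScoringError("distribution_summary needs a non-empty table")
    x = table[metric].to_numpy(dtype=float)
    sd_defined = len(x) > 1
    counts, edges = np.histogram(x, bins=bins)
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return SummaryStats(
        n=len(x),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if sd_defined else 0.0,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        hist_counts=counts.tolist(),
        hist_edges=edges.tolist(),
        sd_defined=sd_defined,
    )
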