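"""Activity→MET compendium: the lookup table that rates each diary activity.

Each activity carries a MET intensity (multiple of resting metabolic rate)
and belongs to one of four reported behaviour categories — household,
transportation, work, leisure/sports — or to an internal fifth category,
``uncategorized``, for behaviours (sleep, meals, grooming) that count toward
total MET but never toward the four category totals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

CATEGORIES = ("household", "transportation", "work", "leisure_sports", "uncategorized")
#: The four categories participants record against; excludes sleep/personal care.
REPORTED_CATEGORIES = CATEGORIES[:4]

MET_MIN = 0.9  # sleep, by convention the resting floor
MET_MAX = 18.0

_FIELDS = ("code", "label", "category", "subcategory", "met")


class CompendiumError(ValueError):
    """Raised for an invalid compendium file or a failed activity lookup."""


@dataclass(frozen=True)
class Activity:
    """One compendium row: a codeable behaviour with its MET intensity."""

    code: str
    label: str
    category: str
    subcategory: str
    met: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CompendiumError(
                f"activity {self.code!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if not (MET_MIN <= self.met <= MET_MAX):
            raise CompendiumError(
                f"activity {self.code!r}: MET {self.met} outside [{MET_MIN}, {MET_MAX}]"
            )


class Compendium:
    """A validated, queryable collection of activities."""

    def __init__(self, activities: list[Activity], version: str = "unversioned"):
        self.version = version
        self.activities = list(activities)
        self._by_code: dict[str, Activity] = {}
        for act in self.activities:
            if act.code in self._by_code:
                raise CompendiumError(f"duplicate activity code {act.code!r}")
            self._by_code[act.code] = act

    def __len__(self) -> int:
        return len(self.activities)

    def __iter__(self) -> Iterator[Activity]:
        return iter(self.activities)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def lookup(self, code: str) -> Activity:
        try:
            return self._by_code[code]
        except KeyError:
            raise CompendiumError(f"unknown activity code {code!r}") from None

    @property
    def codes(self) -> list[str]:
        return list(self._by_code)

    def subcategories(self) -> set[str]:
        return {a.subcategory for a in self.activities}

    def n_reported(self) -> int:
        """Number of activities in the four reported categories."""
        return sum(a.category in REPORTED_CATEGORIES for a in self.activities)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.activities], columns=list(_FIELDS))


def load_compendium(source: str | Path, version: str | None = None) -> Compendium:
    """Read a compendium CSV (``code,label,category,subcategory,met``).

    Raises :class:`CompendiumError` on a missing column, duplicate code,
    unknown category, or a MET outside [0.9, 18.0].
    """
    df = pd.read_csv(source, dtype={"code": str})
    missing = [c for c in _FIELDS if c not in df.columns]
    if missing:
        raise CompendiumError(f"compendium file missing columns: {missing}")
    acts = [
        Activity(
            code=row.code,
            label=row.label,
            category=row.category,
            subcategory=row.subcategory,
            met=float(row.met),
        )
        for row in df.itertuples()
    ]
    if version is None:
        version = Path(source).stem
    return Compendium(acts, version=version)


def write_compendium(compendium: Compendium, dest: str | Path) -> None:
    compendium.to_frame().to_csv(dest, index=False)


def default_compendium() -> Compendium:
    """The packaged 91-activity compendium (plus sleep/personal-care entries).

    The activity list and MET assignments follow standard compendium
    conventions; it is a stand-in for any site-specific menu and is fully
    replaceable via :func:`load_compendium`.
    """
    ref = importlib.resources.files("metdiary.data") / "compendium_v1.csv"
    with importlib.resources.as_file(ref) as path:
        return load_compendium(path, version="v1")
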