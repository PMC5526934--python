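"""Record types shared across pipeline stages.

All dates follow the biological-year convention of boreal caribou
monitoring: a biological year labelled Y runs 1 April Y to 31 March Y+1.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict

from .errors import MalformedRecordError

FATES = ("dead", "censored", "alive_at_year_end")


def biological_year(d: dt.date) -> int:
    """Label of the biological year (1 Apr - 31 Mar) containing date `d`."""
    return d.year if (d.month, d.day) >= (4, 1) else d.year - 1


def biological_year_start(year: int) -> dt.date:
    return dt.date(year, 4, 1)


def biological_year_end(year: int) -> dt.date:
    return dt.date(year + 1, 3, 31)


@dataclass
class CollarRecord:
    """One telemetry monitoring interval of a marked adult female.

    Raw histories may span several biological years; after
    :func:`caribou_pva.telemetry_survival.split_biological_years` each record
    lies within a single 1 Apr - 31 Mar window.
    """

    animal_id: str
    population: str
    entry_date: dt.date
    exit_date: dt.date
    fate: str  # "dead" | "censored" | "alive_at_year_end"

    def __post_init__(self):
        if self.fate not in FATES:
            raise MalformedRecordError(f"unknown fate {self.fate!r}")
        if self.exit_date < self.entry_date:
            raise MalformedRecordError(
                f"animal {self.animal_id}: exit {self.exit_date} before entry {self.entry_date}"
            )


@dataclass
class SurveyRecord:
    """One late-winter aerial-survey classification count for a population-year."""

    population: str
    year: int
    n_calves: int
    n_adult_females: int
    n_adult_males: int
    n_adult_unclassified: int = 0

    def __post_init__(self):
        for name in ("n_calves", "n_adult_females", "n_adult_males", "n_adult_unclassified"):
            if getattr(self, name) < 0:
                raise MalformedRecordError(f"{name} < 0 in survey {self.population}/{self.year}")

    @property
    def total_individuals(self) -> int:
        return self.n_calves + self.n_adult_females + self.n_adult_males + self.n_adult_unclassified


@dataclass
class PopulationRange:
    """A population's productivity index and per-year disturbance trajectory.

    P is the proportion of potentially productive forest stands in the range;
    D_by_year maps biological-year labels to the proportion of total
    disturbance (fire, cuts, roads, buffered, overlap counted once).
    """

    population: str
    P: float
    D_by_year: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.P <= 1.0:
            raise MalformedRecordError(f"P={self.P} outside [0, 1]")
        for y, d in self.D_by_year.items():
            if not 0.0 <= d <= 1.0:
                raise MalformedRecordError(f"D={d} outside [0, 1] in year {y}")


@dataclass
class StandPixel:
    """Forest-inventory attributes of one 250-m pixel."""

    age: float
    height: float
    canopy_cover_raw: float
    treed_fraction: float
    deciduous_raw: float
    vegetated_fraction: float
    P: float


def ranges_by_population(ranges) -> Dict[str, PopulationRange]:
    """Index a list of PopulationRange by population id (dicts pass through)."""
    if isinstance(ranges, dict):
        return ranges
    return {r.population: r for r in ranges}
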