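"""Annual adult-female survival from collar telemetry.

Implements the staggered-entry Kaplan-Meier estimator on biological years
(1 April - 31 March): animals enter the at-risk pool at their collaring
date, are removed at death or at their last known-alive location
(right-censoring), and each population-year with at least six monitored
females yields one annual survival estimate weighted by the number of
monitored females.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .datatypes import (
    CollarRecord,
    biological_year,
    biological_year_end,
    biological_year_start,
)
from .errors import FilteredOut, InconsistentDataError, MalformedRecordError
from .reference import MIN_COLLARED_PER_YEAR

__all__ = [
    "AnnualSurvivalEstimate",
    "split_biological_years",
    "km_survival",
    "km_annual_survival",
    "annual_survival_estimates",
]


@dataclass
class AnnualSurvivalEstimate:
    """Kaplan-Meier annual survival for one population-year.

    n_females (the number of distinct females monitored at any point in the
    year) is the precision weight used when modelling survival against
    landscape covariates.
    """

    population: str
    year: int
    S_hat: float
    n_females: int
    n_deaths: int


def split_biological_years(records: Iterable[CollarRecord]) -> List[CollarRecord]:
    """Cut multi-year collar histories at 31 March / 1 April boundaries.

    An animal alive across a boundary yields a record with fate
    ``alive_at_year_end`` and a fresh entry on the following 1 April; the
    final segment keeps the original fate.
    """
    out: List[CollarRecord] = []
    for rec in records:
        if rec.exit_date < rec.entry_date:
            raise MalformedRecordError(
                f"animal {rec.animal_id}: exit before entry"
            )
        entry = rec.entry_date
        while True:
            year = biological_year(entry)
            yend = biological_year_end(year)
            if rec.exit_date <= yend:
                out.append(
                    CollarRecord(rec.animal_id, rec.population, entry, rec.exit_date, rec.fate)
                )
                break
            out.append(
                CollarRecord(rec.animal_id, rec.population, entry, yend, "alive_at_year_end")
            )
            entry = biological_year_start(year + 1)
    return out


def km_survival(
    entry: Sequence[float], exit: Sequence[float], event: Sequence[bool]
) -> Tuple[float, int]:
    """Staggered-entry Kaplan-Meier survival over one interval.

    Times are on an arbitrary common scale (here: days since 1 April). The
    product runs over distinct death times t with risk set
    ``{i : entry_i < t <= exit_i}``; tied deaths form a single step and
    deaths are processed before removals tied at the same time.

    Returns ``(S_hat, n_deaths)``.
    """
    entry = np.asarray(entry, dtype=float)
    exit = np.asarray(exit, dtype=float)
    event = np.asarray(event, dtype=bool)
    if np.any(exit < entry):
        raise MalformedRecordError("exit before entry")
    death_times = np.unique(exit[event])
    s = 1.0
    n_deaths = int(event.sum())
    for t in death_times:
        at_risk = int(np.sum((entry < t) & (exit >= t)))
        d = int(np.sum(event & (exit == t)))
        if at_risk < d or at_risk == 0:
            raise InconsistentDataError(
                f"risk set of size {at_risk} cannot support {d} deaths at t={t}"
            )
        s *= 1.0 - d / at_risk
    return s, n_deaths


def km_annual_survival(
    records: Iterable[CollarRecord],
    population: str,
    year: int,
    min_animals: int = MIN_COLLARED_PER_YEAR,
) -> AnnualSurvivalEstimate:
    """Annual survival for one population-year from year-split records.

    Raises :class:`FilteredOut` when fewer than `min_animals` distinct
    females contributed that year (the monitoring filter of the analysis).
    """
    ystart = biological_year_start(year)
    sel = [
        r
        for r in records
        if r.population == population and biological_year(r.entry_date) == year
    ]
    animals = {r.animal_id for r in sel}
    if len(animals) < min_animals:
        raise FilteredOut(
            f"{population}/{year}: only {len(animals)} females monitored (< {min_animals})"
        )
    entry = [(r.entry_date - ystart).days for r in sel]
    exit = [(r.exit_date - ystart).days for r in sel]
    event = [r.fate == "dead" for r in sel]
    s, n_deaths = km_survival(entry, exit, event)
    return AnnualSurvivalEstimate(
        population=population,
        year=year,
        S_hat=s,
        n_females=len(animals),
        n_deaths=n_deaths,
    )


def annual_survival_estimates(
    records: Iterable[CollarRecord],
    min_animals: int = MIN_COLLARED_PER_YEAR,
) -> Tuple[List[AnnualSurvivalEstimate], List[Dict]]:
    """All per-population-year estimates, plus a log of filtered-out cells.

    Input records must already be split into biological years.
    """
    by_cell: Dict[Tuple[str, int], List[CollarRecord]] = {}
    for r in records:
        by_cell.setdefault((r.population, biological_year(r.entry_date)), []).append(r)
    estimates: List[AnnualSurvivalEstimate] = []
    filter_log: List[Dict] = []
    for population, year in sorted(by_cell):
        try:
            estimates.append(
                km_annual_survival(by_cell[(population, year)], population, year, min_animals)
            )
        except FilteredOut as exc:
            filter_log.append(
                {
                    "stage": "survival",
                    "population": population,
                    "year": year,
                    "reason": exc.reason,
                }
            )
    return estimates, filter_log
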