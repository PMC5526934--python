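"""Recruitment observations from aerial-survey classification counts.

Turns raw calf / adult-female / adult-male / unclassified-adult counts into
calf-per-female recruitment ratios, applying the sex-ratio correction for
unclassified adults and the minimum-survey-size filter, and attaching the
lagged disturbance covariate (calves counted in late winter reflect the
previous year's disturbance exposure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .datatypes import PopulationRange, SurveyRecord, ranges_by_population
from .errors import FilteredOut, MissingCovariateError, UndefinedRatioError
from .reference import ASSUMED_FEMALE_FRACTION, MIN_SURVEY_INDIVIDUALS

__all__ = ["RecruitmentObservation", "correct_sex_ratio", "recruitment_observation",
           "recruitment_observations"]

# Below this share of unclassified adults the survey's own sexed counts set
# the female fraction; at or above it the regional 65/35 assumption is used.
UNCLASSIFIED_THRESHOLD = 0.10


@dataclass
class RecruitmentObservation:
    """One calf/female ratio with its precision weight and lagged covariate."""

    population: str
    year: int
    R: float                      # calves per corrected adult female
    n_females_corrected: float    # model weight
    D_lagged: float               # disturbance of the year preceding the survey


def correct_sex_ratio(record: SurveyRecord) -> float:
    """Corrected adult-female count: observed females plus their share of
    unclassified adults.

    Unclassified adults are apportioned by the survey's observed female
    fraction F/(F+M) when fewer than 10% of adults were unclassified, and by
    the regional assumption of 65% females otherwise.
    """
    F, M, U = record.n_adult_females, record.n_adult_males, record.n_adult_unclassified
    adults = F + M + U
    if adults == 0:
        raise UndefinedRatioError(
            f"survey {record.population}/{record.year}: no adults counted"
        )
    if U / adults < UNCLASSIFIED_THRESHOLD:
        f = F / (F + M)  # F+M > 0 here, else U/adults == 1
    else:
        f = ASSUMED_FEMALE_FRACTION
    return F + f * U


def recruitment_observation(
    record: SurveyRecord,
    ranges,
    min_individuals: int = MIN_SURVEY_INDIVIDUALS,
) -> RecruitmentObservation:
    """One survey record -> one recruitment observation.

    Raises :class:`FilteredOut` when fewer than `min_individuals` caribou
    (calves plus all adults) were observed, and
    :class:`MissingCovariateError` when the range table lacks the preceding
    year's disturbance.
    """
    by_pop: Dict[str, PopulationRange] = ranges_by_population(ranges)
    if record.total_individuals < min_individuals:
        raise FilteredOut(
            f"{record.population}/{record.year}: {record.total_individuals} "
            f"individuals observed (< {min_individuals})"
        )
    nf = correct_sex_ratio(record)
    rg = by_pop.get(record.population)
    if rg is None or (record.year - 1) not in rg.D_by_year:
        raise MissingCovariateError(
            f"no disturbance value for {record.population} in year {record.year - 1}"
        )
    return RecruitmentObservation(
        population=record.population,
        year=record.year,
        R=record.n_calves / nf,
        n_females_corrected=nf,
        D_lagged=rg.D_by_year[record.year - 1],
    )


def recruitment_observations(
    records: Iterable[SurveyRecord],
    ranges,
    min_individuals: int = MIN_SURVEY_INDIVIDUALS,
) -> Tuple[List[RecruitmentObservation], List[Dict]]:
    """Batch conversion with a log of every survey filtered out and why."""
    obs: List[RecruitmentObservation] = []
    filter_log: List[Dict] = []
    for rec in records:
        try:
            obs.append(recruitment_observation(rec, ranges, min_individuals))
        except FilteredOut as exc:
            filter_log.append(
                {
                    "stage": "recruitment",
                    "population": rec.population,
                    "year": rec.year,
                    "reason": exc.reason,
                }
            )
    return obs, filter_log
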