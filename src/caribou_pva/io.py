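"""CSV / TSV / JSON schemas for every pipeline artefact.

All tables are UTF-8 CSV with a header row, ISO-8601 dates, "." decimal
separator and proportions as decimals in [0, 1]. Floats are written with a
fixed repr so identical runs produce byte-identical files.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .datatypes import CollarRecord, PopulationRange, StandPixel, SurveyRecord
from .survey_processing import RecruitmentObservation
from .telemetry_survival import AnnualSurvivalEstimate

FLOAT_FORMAT = "%.10g"


def _write(frame: pd.DataFrame, path, sep=",") -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT, sep=sep, lineterminator="\n")


# -- collars ---------------------------------------------------------------

def collars_to_frame(records: Iterable[CollarRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "population": r.population,
                "entry_date": r.entry_date.isoformat(),
                "exit_date": r.exit_date.isoformat(),
                "fate": r.fate,
            }
            for r in records
        ]
    )


def write_collars(records: Iterable[CollarRecord], path) -> None:
    _write(collars_to_frame(records), path)


def read_collars(path) -> List[CollarRecord]:
    frame = pd.read_csv(path, dtype=str)
    return [
        CollarRecord(
            animal_id=row.animal_id,
            population=row.population,
            entry_date=dt.date.fromisoformat(row.entry_date),
            exit_date=dt.date.fromisoformat(row.exit_date),
            fate=row.fate,
        )
        for row in frame.itertuples()
    ]


# -- surveys ---------------------------------------------------------------

def surveys_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": r.population,
                "year": r.year,
                "n_calves": r.n_calves,
                "n_adult_females": r.n_adult_females,
                "n_adult_males": r.n_adult_males,
                "n_adult_unclassified": r.n_adult_unclassified,
            }
            for r in records
        ]
    )


def write_surveys(records: Iterable[SurveyRecord], path) -> None:
    _write(surveys_to_frame(records), path)


def read_surveys(path) -> List[SurveyRecord]:
    frame = pd.read_csv(path)
    return [
        SurveyRecord(
            population=str(row.population),
            year=int(row.year),
            n_calves=int(row.n_calves),
            n_adult_females=int(row.n_adult_females),
            n_adult_males=int(row.n_adult_males),
            n_adult_unclassified=int(row.n_adult_unclassified),
        )
        for row in frame.itertuples()
    ]


# -- ranges (long format: one row per population-year) ---------------------

def ranges_to_frame(ranges: Iterable[PopulationRange]) -> pd.DataFrame:
    rows = []
    for r in ranges:
        for year in sorted(r.D_by_year):
            rows.append(
                {"population": r.population, "P": r.P, "year": year, "D": r.D_by_year[year]}
            )
    return pd.DataFrame(rows)


def write_ranges(ranges: Iterable[PopulationRange], path) -> None:
    _write(ranges_to_frame(ranges), path)


def read_ranges(path) -> List[PopulationRange]:
    frame = pd.read_csv(path)
    out: Dict[str, PopulationRange] = {}
    for row in frame.itertuples():
        pop = str(row.population)
        if pop not in out:
            out[pop] = PopulationRange(pop, float(row.P), {})
        out[pop].D_by_year[int(row.year)] = float(row.D)
    return list(out.values())


# -- stand pixels ----------------------------------------------------------

def pixels_to_frame(pixels: Iterable[StandPixel]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pixels])


def write_pixels(pixels: Iterable[StandPixel], path) -> None:
    _write(pixels_to_frame(pixels), path)


def read_pixels(path) -> List[StandPixel]:
    frame = pd.read_csv(path)
    return [
        StandPixel(
            age=float(row.age),
            height=float(row.height),
            canopy_cover_raw=float(row.canopy_cover_raw),
            treed_fraction=float(row.treed_fraction),
            deciduous_raw=float(row.deciduous_raw),
            vegetated_fraction=float(row.vegetated_fraction),
            P=float(row.P),
        )
        for row in frame.itertuples()
    ]


# -- derived tables --------------------------------------------------------

def survival_estimates_to_frame(estimates: Iterable[AnnualSurvivalEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": e.population,
                "year": e.year,
                "S_hat": e.S_hat,
                "n_females": e.n_females,
                "n_deaths": e.n_deaths,
            }
            for e in estimates
        ]
    )


def write_survival_estimates(estimates, path) -> None:
    _write(survival_estimates_to_frame(estimates), path)


def recruitment_to_frame(observations: Iterable[RecruitmentObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": o.population,
                "year": o.year,
                "R": o.R,
                "n_females_corrected": o.n_females_corrected,
                "D_lagged": o.D_lagged,
            }
            for o in observations
        ]
    )


def write_recruitment(observations, path) -> None:
    _write(recruitment_to_frame(observations), path)


def write_filter_log(entries: Sequence[Dict], path) -> None:
    cols = ["stage", "population", "year", "pixel", "reason"]
    frame = pd.DataFrame(entries)
    for c in cols:
        if c not in frame.columns:
            frame[c] = pd.NA
    _write(frame[cols], path)


def write_surface(table: pd.DataFrame, path) -> None:
    _write(table, path, sep="\t")


def write_threshold_curve(curve, path) -> None:
    _write(curve.to_frame(), path, sep="\t")
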