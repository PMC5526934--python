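"""Synthetic monitoring data with the statistical structure the pipeline assumes.

Generates the four inputs of the demographic analysis — collar telemetry
histories, aerial-survey classification counts, range covariate tables and
forest-inventory stand pixels — from logit-linear vital-rate models in
landscape disturbance (D) and forest productivity (P), with population
random intercepts, staggered collar entry and right-censoring. Defaults
reproduce the study conditions of the six-population eastern Canadian
monitoring program: the published coefficient estimates as truth, D in
[0.22, 0.78], P in [0.04, 0.85], 6-22 collared females and 50-252 observed
females per survey.

Everything is driven by one integer seed; identical configurations give
byte-identical tables.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from typing import List, Sequence, Tuple

import numpy as np
from scipy.special import expit

from . import reference
from .datatypes import (
    CollarRecord,
    PopulationRange,
    StandPixel,
    SurveyRecord,
    biological_year_end,
    biological_year_start,
)

__all__ = [
    "GeneratorConfig",
    "generate_ranges",
    "generate_collar_histories",
    "generate_surveys",
    "generate_stand_pixels",
]

# Fixed per-stream keys so each generator draws from an independent stream
# of the same seed: generating surveys never perturbs the collar histories.
_STREAM_RANGES = 1
_STREAM_COLLARS = 2
_STREAM_SURVEYS = 3
_STREAM_PIXELS = 4


@dataclass
class GeneratorConfig:
    """Study-design knobs for the synthetic monitoring program.

    The defaults are the study conditions of the source monitoring program:
    six populations followed ten biological years, ~15 collared females per
    population-year (observed range 6-22), 150 observed females per survey
    (observed range 50-252), the published logit-scale coefficients as the
    generating truth, and a population random-intercept SD of 0.2.
    """

    n_populations: int = 6
    years: int = 10
    collared_per_pop_year: int = 15
    females_per_survey: int = 150
    true_beta_survival: Tuple[float, float, float] = tuple(reference.SURVIVAL_BETA)
    true_beta_recruitment: Tuple[float, float, float] = tuple(reference.RECRUITMENT_BETA)
    sigma_pop: float = 0.2
    censor_prob: float = 0.1          # per-year collar loss / non-predation removal
    frac_unclassified: float = 0.08   # expected share of adults left unsexed per survey
    female_frac_true: float = 0.65    # true adult female fraction in surveyed groups
    seed: int = 0
    # secondary design knobs
    start_year: int = 2005
    staggered_entry_frac: float = 0.5   # share of new collars deployed after 1 April
    d_start_range: Tuple[float, float] = (0.22, 0.70)
    d_step_range: Tuple[float, float] = (0.0, 0.02)
    p_range: Tuple[float, float] = reference.P_RANGE
    shared_random_effects: bool = False  # one u_pop for both rates (default: independent)
    n_pixels: int = 2000
    pixel_noise_sd: float = 1.0          # metres, on stand height; proportions use /20

    def __post_init__(self):
        if self.n_populations < 0 or self.years < 1:
            raise ValueError("n_populations must be >= 0 and years >= 1")
        if self.collared_per_pop_year < 1 or self.females_per_survey < 1:
            raise ValueError("counts must be >= 1")
        if self.sigma_pop < 0:
            raise ValueError("sigma_pop must be >= 0")
        for name in ("censor_prob", "frac_unclassified", "staggered_entry_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.female_frac_true < 1.0:
            raise ValueError("female_frac_true must lie in (0, 1)")
        if len(self.true_beta_survival) != 3 or len(self.true_beta_recruitment) != 3:
            raise ValueError("coefficient vectors must have 3 entries")

    def to_dict(self):
        return asdict(self)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _pop_ids(config: GeneratorConfig) -> List[str]:
    return [f"pop_{i + 1:02d}" for i in range(config.n_populations)]


def _random_effects(config: GeneratorConfig, stream: int) -> np.ndarray:
    """Population random intercepts for one vital rate, reproducible per stream."""
    if config.shared_random_effects:
        stream = _STREAM_COLLARS  # reuse the survival draws
    rng = np.random.default_rng([int(config.seed), stream, 77])
    return rng.normal(0.0, config.sigma_pop, config.n_populations)


def generate_ranges(config: GeneratorConfig) -> List[PopulationRange]:
    """Draw one range table: P uniform, D a non-decreasing yearly trajectory.

    Disturbance accumulates (cuts and fires age out only beyond the simulated
    horizon), so D is non-decreasing and clipped to the observed range.
    """
    rng = _rng(config, _STREAM_RANGES)
    lo_p, hi_p = config.p_range
    d_lo, d_hi = reference.D_RANGE
    out = []
    for pop in _pop_ids(config):
        P = float(rng.uniform(lo_p, hi_p))
        d0 = float(rng.uniform(*config.d_start_range))
        steps = rng.uniform(*config.d_step_range, size=config.years - 1)
        traj = np.minimum(d0 + np.concatenate([[0.0], np.cumsum(steps)]), d_hi)
        years = range(config.start_year, config.start_year + config.years)
        out.append(PopulationRange(pop, P, {y: float(d) for y, d in zip(years, traj)}))
    return out


def _year_length(year: int) -> int:
    """Days from 1 April to 31 March (exclusive upper offset)."""
    return (biological_year_end(year) - biological_year_start(year)).days


def generate_collar_histories(
    ranges: Sequence[PopulationRange], config: GeneratorConfig
) -> List[CollarRecord]:
    """Simulate collar telemetry with staggered entry, deaths and censoring.

    Each biological year a population carries `collared_per_pop_year` collars;
    losses (deaths, censoring) are replaced the following year by newly
    collared animals with staggered deployment dates. Within a year an animal
    dies with annual probability 1 - invlogit(b0 + bD*D_t + bP*P + u_pop)
    placed by a constant within-year hazard, and is independently
    right-censored (collar removal, accident) with `censor_prob`; whichever
    simulated date comes first wins, matching Kaplan-Meier risk-set semantics.
    """
    if not ranges:
        raise ValueError("ranges must be non-empty")
    rng = _rng(config, _STREAM_COLLARS)
    b0, bD, bP = config.true_beta_survival
    u = _random_effects(config, _STREAM_COLLARS)
    records: List[CollarRecord] = []
    for ipop, rg in enumerate(ranges):
        counter = 0
        # active animals: (id, current entry date of the whole history)
        active: List[Tuple[str, dt.date]] = []
        for year in sorted(rg.D_by_year):
            L = _year_length(year)
            ystart = biological_year_start(year)
            # replace lost collars
            n_new = max(0, config.collared_per_pop_year - len(active))
            for _ in range(n_new):
                counter += 1
                if rng.uniform() < config.staggered_entry_frac:
                    off = int(rng.integers(1, 183))  # deployed up to ~end of September
                else:
                    off = 0
                active.append((f"{rg.population}_a{counter:04d}", ystart + dt.timedelta(days=off)))
            D = rg.D_by_year[year]
            p_surv = float(expit(b0 + bD * D + bP * rg.P + u[ipop % len(u)]))
            still_active: List[Tuple[str, dt.date]] = []
            for animal_id, entry in active:
                e = (entry - ystart).days if entry >= ystart else 0
                # death offset under constant hazard calibrated to annual p_surv
                if p_surv >= 1.0:
                    death_off = math.inf
                else:
                    rate = -math.log(p_surv) / L
                    t = rng.exponential(1.0 / rate)
                    death_off = e + t
                censor_off = math.inf
                if config.censor_prob > 0 and rng.uniform() < config.censor_prob:
                    censor_off = int(rng.integers(e + 1, L + 1))
                if death_off <= L and death_off <= censor_off:
                    off = min(L, max(e + 1, math.ceil(death_off)))
                    records.append(
                        CollarRecord(animal_id, rg.population, entry,
                                     ystart + dt.timedelta(days=off), "dead")
                    )
                elif censor_off <= L:
                    records.append(
                        CollarRecord(animal_id, rg.population, entry,
                                     ystart + dt.timedelta(days=int(censor_off)), "censored")
                    )
                else:
                    still_active.append((animal_id, entry))
            active = still_active
        # histories still open at the end of monitoring
        last_year = max(rg.D_by_year)
        for animal_id, entry in active:
            records.append(
                CollarRecord(animal_id, rg.population, entry,
                             biological_year_end(last_year), "alive_at_year_end")
            )
    return records


def generate_surveys(
    ranges: Sequence[PopulationRange], config: GeneratorConfig
) -> List[SurveyRecord]:
    """Simulate late-winter aerial classification counts.

    The calf count is Binomial(n_females, invlogit(b0 + bD*D_{t-1} + bP2*P^2
    + u_pop)): the covariate is the disturbance of the year preceding the
    survey, because calves counted in late winter reflect the previous year's
    reproduction. Males follow from the true adult female fraction; a share
    of adults is left unclassified (sex undetermined from the air).
    """
    if not ranges:
        raise ValueError("ranges must be non-empty")
    rng = _rng(config, _STREAM_SURVEYS)
    b0, bD, bP2 = config.true_beta_recruitment
    u = _random_effects(config, _STREAM_SURVEYS + 10)
    out: List[SurveyRecord] = []
    for ipop, rg in enumerate(ranges):
        years = sorted(rg.D_by_year)
        for year in years[1:]:  # need D of the preceding year
            D_lag = rg.D_by_year[year - 1]
            p_calf = float(expit(b0 + bD * D_lag + bP2 * rg.P**2 + u[ipop % len(u)]))
            nF = config.females_per_survey
            n_calves = int(rng.binomial(nF, p_calf))
            n_adults = int(round(nF / config.female_frac_true))
            nM = n_adults - nF
            nU = int(rng.binomial(n_adults, config.frac_unclassified))
            uF = int(rng.hypergeometric(nF, nM, nU)) if nU > 0 else 0
            out.append(
                SurveyRecord(
                    population=rg.population,
                    year=year,
                    n_calves=n_calves,
                    n_adult_females=nF - uF,
                    n_adult_males=nM - (nU - uF),
                    n_adult_unclassified=nU,
                )
            )
    return out


def generate_stand_pixels(config: GeneratorConfig) -> List[StandPixel]:
    """Simulate forest-inventory pixels for the stand-development analysis.

    Height follows a saturating growth curve whose asymptote and rate both
    increase with productivity P; canopy cover likewise; the deciduous
    fraction is unimodal in stand age with its peak near 20 years and a level
    increasing with P. Raw canopy/deciduous values are diluted by the treed /
    vegetated fraction of the pixel so the cover corrections are exercised.
    """
    rng = _rng(config, _STREAM_PIXELS)
    n = config.n_pixels
    sd_h = config.pixel_noise_sd
    sd_p = config.pixel_noise_sd / 20.0
    age = rng.uniform(0.0, 120.0, n)
    P = rng.uniform(*config.p_range, size=n)
    treed = rng.uniform(0.5, 1.0, n)
    veg = rng.uniform(0.6, 1.0, n)

    h_asym = 8.0 + 12.0 * P
    h_rate = 0.015 + 0.04 * P
    height = h_asym * (1.0 - np.exp(-h_rate * age))
    c_rate = 0.02 + 0.05 * P
    cover = 0.95 * (1.0 - np.exp(-c_rate * age))
    decid = (0.10 + 0.45 * P) * (age / 20.0) * np.exp(1.0 - age / 20.0)

    if sd_h > 0:
        height = height + rng.normal(0.0, sd_h, n)
        cover = cover + rng.normal(0.0, sd_p, n)
        decid = decid + rng.normal(0.0, sd_p, n)
    height = np.maximum(height, 0.0)
    # zero-age stands carry no structure regardless of noise
    height[age == 0.0] = 0.0
    cover[age == 0.0] = 0.0
    canopy_raw = np.clip(cover * treed, 0.0, 1.0)
    decid_raw = np.clip(decid * veg, 0.0, 1.0)
    return [
        StandPixel(
            age=float(age[i]),
            height=float(height[i]),
            canopy_cover_raw=float(canopy_raw[i]),
            treed_fraction=float(treed[i]),
            deciduous_raw=float(decid_raw[i]),
            vegetated_fraction=float(veg[i]),
            P=float(P[i]),
        )
        for i in range(n)
    ]
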