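"""Generator sanity: stated ranges, seeded determinism, model-implied moments."""

import numpy as np
import pytest
from scipy.special import expit, logit

from caribou_pva.datatypes import PopulationRange, biological_year
from caribou_pva.io import collars_to_frame, pixels_to_frame, ranges_to_frame, surveys_to_frame
from caribou_pva.synthetic_data import (
    GeneratorConfig,
    generate_collar_histories,
    generate_ranges,
    generate_stand_pixels,
    generate_surveys,
)
from caribou_pva.telemetry_survival import split_biological_years

from conftest import SEED


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(sigma_pop=-0.1)
    with pytest.raises(ValueError):
        GeneratorConfig(censor_prob=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(female_frac_true=1.0)
    with pytest.raises(ValueError):
        GeneratorConfig(collared_per_pop_year=0)


def test_ranges_within_stated_bounds_and_monotone():
    cfg = GeneratorConfig(n_populations=6, years=10, seed=SEED)
    ranges = generate_ranges(cfg)
    assert len(ranges) == 6
    for rg in ranges:
        assert 0.04 <= rg.P <= 0.85
        traj = [rg.D_by_year[y] for y in sorted(rg.D_by_year)]
        assert all(0.22 <= d <= 0.78 for d in traj)
        assert all(b >= a for a, b in zip(traj, traj[1:]))


def test_zero_populations_gives_empty_table():
    assert generate_ranges(GeneratorConfig(n_populations=0, seed=SEED)) == []


def test_identical_seed_gives_byte_identical_tables():
    a, b = (GeneratorConfig(n_populations=4, years=6, seed=SEED) for _ in range(2))
    ra, rb = generate_ranges(a), generate_ranges(b)
    assert ranges_to_frame(ra).to_csv() == ranges_to_frame(rb).to_csv()
    assert (
        collars_to_frame(generate_collar_histories(ra, a)).to_csv()
        == collars_to_frame(generate_collar_histories(rb, b)).to_csv()
    )
    assert (
        surveys_to_frame(generate_surveys(ra, a)).to_csv()
        == surveys_to_frame(generate_surveys(rb, b)).to_csv()
    )
    assert (
        pixels_to_frame(generate_stand_pixels(a)).to_csv()
        == pixels_to_frame(generate_stand_pixels(b)).to_csv()
    )


def test_certain_censoring_ends_every_history_within_its_year():
    """With per-year censoring certain, no animal survives monitored to a
    year end; deaths can still precede the censor date (the two compete)."""
    cfg = GeneratorConfig(n_populations=2, years=3, censor_prob=1.0, seed=SEED)
    records = generate_collar_histories(generate_ranges(cfg), cfg)
    fates = [r.fate for r in records]
    assert fates and "alive_at_year_end" not in fates
    assert fates.count("censored") > len(fates) / 2


def test_no_deaths_when_hazard_removed_and_censoring_certain():
    cfg = GeneratorConfig(
        n_populations=2, years=3, censor_prob=1.0, sigma_pop=0.0,
        true_beta_survival=(50.0, 0.0, 0.0), seed=SEED,
    )
    records = generate_collar_histories(generate_ranges(cfg), cfg)
    assert records and all(r.fate == "censored" for r in records)


def test_no_deaths_when_survival_probability_is_one():
    # a huge intercept drives the annual survival probability to 1
    cfg = GeneratorConfig(
        n_populations=2, years=3, censor_prob=0.0, sigma_pop=0.0,
        true_beta_survival=(50.0, 0.0, 0.0), seed=SEED,
    )
    records = generate_collar_histories(generate_ranges(cfg), cfg)
    assert records and all(r.fate == "alive_at_year_end" for r in records)


def test_annual_death_frequency_matches_closed_form():
    """Monte-Carlo death frequency converges to 1 - invlogit(linear predictor).

    ~1e5 full-year animal-years at D=0.35, P=0.85 under the published
    survival coefficients; tolerance is 3 binomial standard errors.
    """
    n_pops, years, per = 100, 10, 100
    cfg = GeneratorConfig(
        n_populations=n_pops, years=years, collared_per_pop_year=per,
        sigma_pop=0.0, censor_prob=0.0, staggered_entry_frac=0.0, seed=SEED,
    )
    ranges = [
        PopulationRange(f"pop_{i:03d}", 0.85, {2005 + t: 0.35 for t in range(years)})
        for i in range(n_pops)
    ]
    split = split_biological_years(generate_collar_histories(ranges, cfg))
    p_true = expit(1.67 - 0.77 * 0.35 + 1.22 * 0.85)  # invlogit(2.4375)
    n_years = len(split)
    deaths = sum(r.fate == "dead" for r in split)
    se = np.sqrt(p_true * (1 - p_true) / n_years)
    assert n_years >= 1e5 * 0.95
    assert abs(deaths / n_years - (1 - p_true)) < 3 * se


def test_survey_counts_match_binomial_mean_and_unclassified_rule():
    # constant calf probability 0.45 regardless of covariates
    cfg = GeneratorConfig(
        n_populations=50, years=12, females_per_survey=200, sigma_pop=0.0,
        true_beta_recruitment=(float(logit(0.45)), 0.0, 0.0),
        frac_unclassified=0.0, seed=SEED,
    )
    surveys = generate_surveys(generate_ranges(cfg), cfg)
    assert all(s.n_adult_unclassified == 0 for s in surveys)
    calves = np.array([s.n_calves for s in surveys])
    se_mean = np.sqrt(200 * 0.45 * 0.55 / len(surveys))
    assert abs(calves.mean() - 90.0) < 3 * se_mean


def test_surveys_use_previous_years_disturbance():
    cfg = GeneratorConfig(n_populations=1, years=3, seed=SEED)
    ranges = generate_ranges(cfg)
    surveys = generate_surveys(ranges, cfg)
    years = sorted(ranges[0].D_by_year)
    assert [s.year for s in surveys] == years[1:]  # first year has no lagged D


def test_stand_pixels_age_zero_and_productivity_ordering():
    cfg = GeneratorConfig(n_pixels=500, pixel_noise_sd=0.0, seed=SEED)
    pixels = generate_stand_pixels(cfg)
    for px in pixels:
        assert 0.0 <= px.canopy_cover_raw <= 1.0
        assert 0.0 <= px.deciduous_raw <= 1.0
        if px.age == 0.0:
            assert px.height == 0.0 and px.canopy_cover_raw == 0.0
    # noiseless: within a narrow age band, height increases with P
    band = sorted((p for p in pixels if 40 <= p.age <= 60), key=lambda p: p.P)
    assert len(band) > 20
    lo = np.mean([p.height for p in band[: len(band) // 3]])
    hi = np.mean([p.height for p in band[-len(band) // 3 :]])
    assert hi > lo


def test_collar_histories_keep_target_cohort_size():
    cfg = GeneratorConfig(n_populations=3, years=6, collared_per_pop_year=10, seed=SEED)
    split = split_biological_years(generate_collar_histories(generate_ranges(cfg), cfg))
    counts = {}
    for r in split:
        counts.setdefault((r.population, biological_year(r.entry_date)), set()).add(r.animal_id)
    assert all(len(v) == 10 for v in counts.values())
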