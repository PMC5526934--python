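"""Weighted binomial mixed models: oracles, invariants, bootstrap behaviour."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from caribou_pva.datatypes import PopulationRange
from caribou_pva.errors import RankDeficiencyError, SeparationError
from caribou_pva.glmm import fit_weighted_binomial_glmm
from caribou_pva.survey_processing import RecruitmentObservation
from caribou_pva.telemetry_survival import AnnualSurvivalEstimate
from caribou_pva.vital_rate_models import (
    bootstrap_ci,
    fit_recruitment_model,
    fit_survival_model,
    predict_rate,
)

from conftest import SEED


def _random_dataset(rng, n_groups=5, per=8, sigma=0.0):
    n = n_groups * per
    groups = np.repeat(np.arange(n_groups), per)
    X = np.column_stack([
        np.ones(n),
        rng.uniform(0.2, 0.8, n),
        np.repeat(rng.uniform(0.0, 1.0, n_groups), per),
    ])
    beta = rng.normal(0.0, 0.8, 3)
    u = rng.normal(0.0, sigma, n_groups)
    p = expit(X @ beta + u[groups])
    w = rng.integers(8, 40, n).astype(float)
    y = rng.binomial(w.astype(int), p) / w
    return y, w, X, groups


class TestGLMMEngine:
    def test_matches_weighted_glm_oracle_on_50_random_datasets(self, rng):
        """With the random-intercept variance at zero the mixed fit must equal
        a plain weighted logistic regression to 4 decimals."""
        checked = 0
        for _ in range(50):
            y, w, X, groups = _random_dataset(rng)
            if y.min() == y.max():
                continue
            try:
                res = fit_weighted_binomial_glmm(y, w, X, groups)
            except SeparationError:
                continue
            if res.sigma > 1e-6:  # oracle only defined for the boundary case
                continue
            glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
            np.testing.assert_allclose(res.beta, glm.params, atol=1e-4)
            checked += 1
        assert checked >= 30

    def test_matches_lme4_glmer_with_quadrature(self, tmp_path):
        """Cross-check a sigma > 0 fit against R/lme4 glmer at nAGQ=15."""
        rng = np.random.default_rng(SEED)
        y, w, X, groups = _random_dataset(rng, n_groups=10, per=10, sigma=0.4)
        res = fit_weighted_binomial_glmm(y, w, X, groups, nodes=15)
        df = pd.DataFrame({"y": y, "w": w, "d": X[:, 1], "pp": X[:, 2], "g": groups})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rcode = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(y ~ d + pp + (1|g), data=d, family=binomial, weights=w, nAGQ=15);"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))))"
        )
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        vals = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(res.beta, vals[:3], atol=5e-3)
        assert res.sigma == pytest.approx(vals[3], abs=5e-3)

    def test_doubling_weights_leaves_point_estimates_unchanged(self, rng):
        """Weights scale information, not location (boundary-sigma case)."""
        y, w, X, groups = _random_dataset(rng)
        r1 = fit_weighted_binomial_glmm(y, w, X, groups)
        r2 = fit_weighted_binomial_glmm(y, 2 * w, X, groups)
        if max(r1.sigma, r2.sigma) < 1e-6:
            np.testing.assert_allclose(r1.beta, r2.beta, atol=1e-6)

    def test_rank_deficient_design_rejected(self):
        n = 20
        X = np.column_stack([np.ones(n), np.linspace(0.2, 0.8, n), np.full(n, 0.5)])
        y = np.linspace(0.3, 0.9, n)
        with pytest.raises(RankDeficiencyError):
            fit_weighted_binomial_glmm(y, np.full(n, 10.0), X, np.zeros(n, dtype=int))

    def test_boundary_response_raises_separation(self):
        n = 20
        r = np.random.default_rng(SEED)
        X = np.column_stack([np.ones(n), np.linspace(0.2, 0.8, n), r.uniform(0, 1, n)])
        with pytest.raises(SeparationError):
            fit_weighted_binomial_glmm(
                np.zeros(n), np.full(n, 10.0), X, np.repeat([0, 1], 10)
            )


def _survival_data(rng, n_pops=8, years=6, sigma=0.0, beta=(1.67, -0.77, 1.22), w=15):
    ranges, estimates = [], []
    u = rng.normal(0.0, sigma, n_pops)
    for i in range(n_pops):
        P = rng.uniform(0.04, 0.85)
        D = {2005 + t: rng.uniform(0.22, 0.78) for t in range(years)}
        ranges.append(PopulationRange(f"p{i}", P, D))
        for year, d in D.items():
            p = expit(beta[0] + beta[1] * d + beta[2] * P + u[i])
            estimates.append(
                AnnualSurvivalEstimate(f"p{i}", year, rng.binomial(w, p) / w, w, 0)
            )
    return estimates, ranges


class TestVitalRateFits:
    def test_survival_fit_single_population_rank_deficient(self, rng):
        estimates, ranges = _survival_data(rng, n_pops=1, years=8)
        with pytest.raises(RankDeficiencyError):
            fit_survival_model(estimates, ranges)

    def test_all_zero_calves_is_separation(self):
        obs = [
            RecruitmentObservation(f"p{i % 3}", 2005 + i, 0.0, 100.0, 0.3 + 0.05 * i)
            for i in range(8)
        ]
        ranges = [PopulationRange(f"p{i}", 0.3 + 0.2 * i, {}) for i in range(3)]
        with pytest.raises(SeparationError):
            fit_recruitment_model(obs, ranges)

    def test_integer_trials_mode_close_to_ratio_mode(self, rng):
        estimates, ranges = _survival_data(rng)
        obs = [
            RecruitmentObservation(e.population, e.year, min(e.S_hat * 0.5, 1.0),
                                   100.3, 0.25 + 0.02 * (e.year - 2005))
            for e in estimates
        ]
        m1 = fit_recruitment_model(obs, ranges, trials="weights")
        m2 = fit_recruitment_model(obs, ranges, trials="integer")
        np.testing.assert_allclose(m1.beta, m2.beta, atol=0.05)


class TestPredictRate:
    def test_published_recruitment_predictions(self, recruitment_model):
        assert predict_rate(recruitment_model, 0.35, 0.21) == pytest.approx(0.14, abs=5e-3)
        assert predict_rate(recruitment_model, 0.35, 0.85) == pytest.approx(0.456, abs=1e-3)

    def test_zero_linear_predictor_gives_half(self, survival_model):
        m = survival_model
        # choose D so the predictor vanishes at P=0: b0 + bD*D = 0
        D = -m.beta[0] / m.beta[1]
        assert predict_rate(m, float(D), 0.0) == pytest.approx(0.5)

    def test_monotone_decreasing_in_D_increasing_in_P(self, survival_model, recruitment_model):
        D = np.linspace(0.0, 1.0, 41)
        for m in (survival_model, recruitment_model):
            s = predict_rate(m, D, np.full_like(D, 0.5))
            assert np.all(np.diff(s) < 0)
            P = np.linspace(0.01, 1.0, 41)
            s = predict_rate(m, np.full_like(P, 0.35), P)
            assert np.all(np.diff(s) > 0)


class TestBootstrap:
    def test_two_iterations_bracket_min_and_max(self, rng):
        estimates, ranges = _survival_data(rng)
        model = fit_survival_model(estimates, ranges)
        cis, draws = bootstrap_ci(model, n_iter=2, seed=SEED, return_draws=True)
        # with two draws the percentile bounds are exactly min and max
        for j, ci in enumerate(cis):
            assert ci.lower == pytest.approx(draws[:, j].min())
            assert ci.upper == pytest.approx(draws[:, j].max())

    def test_huge_weights_shrink_interval(self, rng):
        """Interval widths collapse as the information grows (consistency)."""
        est_small, ranges_small = _survival_data(rng, w=15)
        est_huge, ranges_huge = _survival_data(rng, w=20000)
        w_small = [
            ci.upper - ci.lower
            for ci in bootstrap_ci(fit_survival_model(est_small, ranges_small),
                                   n_iter=30, seed=SEED)
        ]
        w_huge = [
            ci.upper - ci.lower
            for ci in bootstrap_ci(fit_survival_model(est_huge, ranges_huge),
                                   n_iter=30, seed=SEED)
        ]
        assert max(w_huge) < 0.25
        assert all(h < s / 4 for h, s in zip(w_huge, w_small))
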