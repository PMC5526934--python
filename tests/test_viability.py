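"""Growth-rate algebra, threshold solving and uncertainty propagation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caribou_pva.errors import DomainError, UncertaintyUnavailableError
from caribou_pva.vital_rate_models import VitalRateModel
from caribou_pva.viability import (
    _draw_betas,
    _lambda_from_betas,
    _solve_thresholds,
    classify_point,
    confident_threshold,
    lambda_f,
    mean_threshold,
    recruitment_to_female,
    threshold_draws,
    viability_surface,
)

from conftest import SEED


class TestAlgebra:
    @pytest.mark.parametrize(
        "R, expected", [(0.0, 0.0), (2.0, 0.5), (0.45, 0.225 / 1.225)]
    )
    def test_female_recruitment_values(self, R, expected):
        assert recruitment_to_female(R) == pytest.approx(expected)

    @given(st.floats(0.0, 50.0))
    def test_female_recruitment_bounded_and_monotone(self, R):
        rf = recruitment_to_female(R)
        assert 0.0 <= rf < 1.0
        assert recruitment_to_female(R + 0.1) > rf

    def test_negative_ratio_rejected(self):
        with pytest.raises(DomainError):
            recruitment_to_female(-0.1)

    @pytest.mark.parametrize("S, R, expected", [(1.0, 0.0, 1.0), (0.9, 2.0, 1.8)])
    def test_lambda_values(self, S, R, expected):
        assert lambda_f(S, R) == pytest.approx(expected)

    @given(st.floats(0.01, 5.0))
    def test_lambda_unity_boundary(self, R):
        # lambda_f = 1 exactly when S = 1/(1 + R/2)
        assert lambda_f(1.0 / (1.0 + R / 2.0), R) == pytest.approx(1.0)

    def test_nonpositive_survival_rejected(self):
        with pytest.raises(DomainError):
            lambda_f(0.0, 0.5)

    def test_lambda_increasing_in_survival_and_recruitment(self):
        assert lambda_f(0.9, 0.5) > lambda_f(0.8, 0.5)
        assert lambda_f(0.9, 0.6) > lambda_f(0.9, 0.5)


class TestMeanThreshold:
    def test_agrees_with_grid_scan_oracle(self, survival_model, recruitment_model):
        """Bisection root vs a brute-force 1e-4-step scan of the same
        definition (largest D with lambda_f >= 1)."""
        for P in (0.21, 0.5, 0.85):
            res = mean_threshold(survival_model, recruitment_model, P)
            grid = np.arange(0.0, 1.0 + 1e-12, 1e-4)
            lam = _lambda_from_betas(
                survival_model.beta, recruitment_model.beta, grid, P
            )
            d_grid = grid[lam >= 1.0].max() if np.any(lam >= 1.0) else 0.0
            assert res.d_star == pytest.approx(d_grid, abs=2e-4)

    def test_always_viable_when_survival_forced_to_one(self, recruitment_model):
        s = VitalRateModel(
            rate="survival", beta=np.array([50.0, 0.0, 0.0]),
            names=("intercept", "disturbance", "productivity"),
            vcov=np.zeros((3, 3)), sigma_pop=0.0, n_obs=0,
        )
        res = mean_threshold(s, recruitment_model, 0.5)
        assert res.d_star == 1.0 and res.status == "viable_throughout"

    def test_threshold_increases_with_productivity(self, survival_model, recruitment_model):
        d_low = mean_threshold(survival_model, recruitment_model, 0.2).d_star
        d_high = mean_threshold(survival_model, recruitment_model, 0.8).d_star
        assert d_high > d_low


class TestConfidentThreshold:
    def test_zero_covariance_degenerates_to_mean_threshold(
        self, survival_model, recruitment_model
    ):
        s = VitalRateModel(
            rate="survival", beta=survival_model.beta, names=survival_model.names,
            vcov=np.zeros((3, 3)), sigma_pop=0.0, n_obs=0,
        )
        r = VitalRateModel(
            rate="recruitment", beta=recruitment_model.beta, names=recruitment_model.names,
            vcov=np.zeros((3, 3)), sigma_pop=0.0, n_obs=0,
        )
        d95 = confident_threshold(s, r, 0.6, n_sim=200, seed=SEED)
        assert d95 == pytest.approx(mean_threshold(s, r, 0.6).d_star, abs=1e-9)

    def test_never_exceeds_mean_threshold(self, survival_model, recruitment_model):
        for P in (0.2, 0.5, 0.85):
            for seed in (SEED, SEED + 1):
                d95 = confident_threshold(
                    survival_model, recruitment_model, P, n_sim=2000, seed=seed
                )
                assert d95 <= mean_threshold(survival_model, recruitment_model, P).d_star + 1e-9

    def test_agrees_with_pooled_grid_definition_on_same_draws(
        self, survival_model, recruitment_model
    ):
        """The 5th percentile of per-draw thresholds equals the largest D at
        which >= 95% of the same draws give lambda_f >= 1 (dual definition)."""
        P, n_sim = 0.6, 2000
        rng = np.random.default_rng(SEED)
        sb = _draw_betas(survival_model, n_sim, rng)
        rb = _draw_betas(recruitment_model, n_sim, rng)
        per_draw, _ = _solve_thresholds(sb, rb, P)
        d95 = float(np.quantile(per_draw, 0.05))
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-3)
        lam = _lambda_from_betas(sb[:, None, :], rb[:, None, :], grid[None, :], P)
        frac_ok = (lam >= 1.0).mean(axis=0)
        pooled = grid[frac_ok >= 0.95].max() if np.any(frac_ok >= 0.95) else 0.0
        assert d95 == pytest.approx(pooled, abs=2e-3)

    def test_stable_across_seeds_at_10k_draws(self, survival_model, recruitment_model):
        a = confident_threshold(survival_model, recruitment_model, 0.5, n_sim=10000, seed=1)
        b = confident_threshold(survival_model, recruitment_model, 0.5, n_sim=10000, seed=2)
        assert abs(a - b) < 0.01

    def test_missing_covariance_rejected(self, survival_model, recruitment_model):
        bare = VitalRateModel(
            rate="survival", beta=survival_model.beta, names=survival_model.names,
            vcov=None, sigma_pop=0.0, n_obs=0,
        )
        with pytest.raises(UncertaintyUnavailableError):
            threshold_draws(bare, recruitment_model, 0.5, n_sim=200, seed=SEED)

    def test_too_few_draws_rejected(self, survival_model, recruitment_model):
        with pytest.raises(ValueError):
            threshold_draws(survival_model, recruitment_model, 0.5, n_sim=50, seed=SEED)


class TestSurface:
    def test_surface_reproduces_published_recruitment_points(
        self, survival_model, recruitment_model
    ):
        surf = viability_surface(
            survival_model, recruitment_model,
            D_grid=[0.35], P_grid=[0.21, 0.85], n_sim=200, seed=SEED,
        )
        t = surf.table.set_index("P")
        assert t.loc[0.21, "R"] == pytest.approx(0.14, abs=5e-3)
        assert t.loc[0.85, "R"] == pytest.approx(0.456, abs=1e-3)

    def test_degenerate_grid_single_point(self, survival_model, recruitment_model):
        surf = viability_surface(
            survival_model, recruitment_model, D_grid=[0.3], P_grid=[0.5],
            n_sim=200, seed=SEED,
        )
        assert len(surf.table) == 1
        row = surf.table.iloc[0]
        assert row.lambda_f == pytest.approx(row.S_f * (1 + row.R / 2))

    def test_classification_flips_once_crossing_the_curve(
        self, survival_model, recruitment_model
    ):
        P = 0.7
        d_star = mean_threshold(survival_model, recruitment_model, P).d_star
        assert classify_point(survival_model, recruitment_model, d_star, P) == "stable"
        labels = [
            classify_point(survival_model, recruitment_model, d, P)
            for d in np.linspace(0.0, 1.0, 101)
        ]
        # increase ... (stable) ... decline, with a single switch
        collapsed = [l for i, l in enumerate(labels) if i == 0 or l != labels[i - 1]]
        assert collapsed in (["increase", "decline"], ["increase", "stable", "decline"])

    def test_empty_grid_rejected(self, survival_model, recruitment_model):
        with pytest.raises(ValueError):
            viability_surface(survival_model, recruitment_model, D_grid=[], P_grid=[0.5])

    def test_curve_confidence_below_mean_everywhere(self, survival_model, recruitment_model):
        surf = viability_surface(
            survival_model, recruitment_model,
            D_grid=np.linspace(0, 1, 11), P_grid=np.linspace(0.1, 0.9, 9),
            n_sim=500, seed=SEED,
        )
        assert np.all(surf.curve.D_star_95 <= surf.curve.D_star_mean + 1e-9)
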