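"""Population growth rate and disturbance thresholds.

The finite annual rate of change of the female population segment is

    lambda_f(D, P) = S_f(D, P) / (1 - R_f(D, P)),

with S_f the annual adult-female survival, R the calf/female ratio and
R_f = (R/2) / (1 + R/2) the female recruitment rate under an even birth sex
ratio; algebraically lambda_f = S_f * (1 + R/2). Because both fitted
disturbance coefficients are negative, lambda_f decreases in D, so the
"withstandable" disturbance D* at a given productivity P is the root of
lambda_f(D, P) = 1. Statistical uncertainty is propagated by simulating
coefficient vectors from the multivariate-normal sampling distribution of
each model's fixed effects (independently across the two models, which were
fitted separately) and solving each draw's threshold: the 95%-confidence
limit is the 5th percentile of the per-draw thresholds — the largest
disturbance at which at least 95% of draws still give lambda_f >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DomainError, UncertaintyUnavailableError
from .vital_rate_models import VitalRateModel, predict_rate

__all__ = [
    "recruitment_to_female",
    "lambda_f",
    "ThresholdResult",
    "ThresholdCurve",
    "ViabilitySurface",
    "mean_threshold",
    "threshold_draws",
    "confident_threshold",
    "viability_surface",
    "classify_point",
]

_BISECT_ITER = 45  # interval width 2^-45 ~ 3e-14, far inside the 1e-6 tolerance


def recruitment_to_female(R):
    """Female-only recruitment rate R_f = (R/2)/(1 + R/2), in [0, 1)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise DomainError("calf/female ratio R must be >= 0")
    out = (R / 2.0) / (1.0 + R / 2.0)
    return float(out) if out.ndim == 0 else out


def lambda_f(S_f, R):
    """Finite annual growth rate of the female segment, S_f/(1 - R_f)."""
    S_f = np.asarray(S_f, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(S_f <= 0) or np.any(S_f > 1):
        raise DomainError("survival S_f must lie in (0, 1]")
    out = S_f / (1.0 - recruitment_to_female(R))
    return float(out) if out.ndim == 0 else out


@dataclass
class ThresholdResult:
    """A solved lambda_f = 1 disturbance level with its boundary status."""

    d_star: float
    status: str  # "interior" | "non_viable_undisturbed" | "viable_throughout"


@dataclass
class ThresholdCurve:
    """Mean and 95%-confidence disturbance limits along a productivity grid."""

    P_grid: np.ndarray
    D_star_mean: np.ndarray
    D_star_95: np.ndarray
    status_mean: list
    n_sim: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "P": self.P_grid,
                "D_star_mean": self.D_star_mean,
                "D_star_95": self.D_star_95,
                "status": self.status_mean,
            }
        )


@dataclass
class ViabilitySurface:
    """Point-estimate lambda_f over a (D, P) grid, plus classifications."""

    table: pd.DataFrame
    curve: ThresholdCurve
    classifications: Optional[pd.DataFrame] = field(default=None)


def _lambda_from_betas(s_beta, r_beta, D, P):
    """lambda_f for (possibly batched) coefficient vectors at scalar/array D."""
    s_beta = np.asarray(s_beta, dtype=float)
    r_beta = np.asarray(r_beta, dtype=float)
    S = expit(s_beta[..., 0] + s_beta[..., 1] * D + s_beta[..., 2] * P)
    R = expit(r_beta[..., 0] + r_beta[..., 1] * D + r_beta[..., 2] * P**2)
    return S * (1.0 + R / 2.0)


def _solve_thresholds(s_betas: np.ndarray, r_betas: np.ndarray, P: float):
    """Per-draw largest D in [0, 1] with lambda_f >= 1 (0 when none).

    Monotone draws (both disturbance coefficients <= 0) are solved by
    vectorized bisection; the rare non-monotone draws fall back to a dense
    grid scan of the same definition.
    """
    B = s_betas.shape[0]
    d_star = np.zeros(B)
    status = np.full(B, "interior", dtype=object)
    lam0 = _lambda_from_betas(s_betas, r_betas, 0.0, P)
    lam1 = _lambda_from_betas(s_betas, r_betas, 1.0, P)
    monotone = (s_betas[:, 1] <= 0) & (r_betas[:, 1] <= 0)

    dead = lam0 < 1.0
    alive = lam1 >= 1.0
    d_star[dead & monotone] = 0.0
    status[dead & monotone] = "non_viable_undisturbed"
    d_star[alive & monotone] = 1.0
    status[alive & monotone] = "viable_throughout"

    solve = monotone & ~dead & ~alive
    if np.any(solve):
        sb, rb = s_betas[solve], r_betas[solve]
        lo = np.zeros(sb.shape[0])
        hi = np.ones(sb.shape[0])
        for _ in range(_BISECT_ITER):
            mid = 0.5 * (lo + hi)
            ge1 = _lambda_from_betas(sb, rb, mid, P) >= 1.0
            lo = np.where(ge1, mid, lo)
            hi = np.where(ge1, hi, mid)
        d_star[solve] = 0.5 * (lo + hi)

    odd = ~monotone
    if np.any(odd):
        grid = np.linspace(0.0, 1.0, 1001)
        lam = _lambda_from_betas(
            s_betas[odd][:, None, :], r_betas[odd][:, None, :], grid[None, :], P
        )
        ge1 = lam >= 1.0
        any_ge = ge1.any(axis=1)
        idx = ge1.shape[1] - 1 - np.argmax(ge1[:, ::-1], axis=1)
        vals = np.where(any_ge, grid[idx], 0.0)
        d_star[odd] = vals
        status[odd] = np.where(
            any_ge, np.where(vals >= 1.0, "viable_throughout", "interior"),
            "non_viable_undisturbed",
        )
    return d_star, status


def mean_threshold(
    survival_model: VitalRateModel, recruitment_model: VitalRateModel, P: float
) -> ThresholdResult:
    """Disturbance level solving lambda_f = 1 from the fixed-effect point
    estimates (bisection; absolute tolerance well below 1e-6 on D)."""
    d, s = _solve_thresholds(
        survival_model.beta[None, :], recruitment_model.beta[None, :], float(P)
    )
    return ThresholdResult(float(d[0]), str(s[0]))


def _draw_betas(model: VitalRateModel, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    if model.vcov is None:
        raise UncertaintyUnavailableError(
            f"{model.rate} model carries no coefficient covariance"
        )
    return rng.multivariate_normal(
        model.beta, model.vcov, size=n_sim, check_valid="ignore", method="eigh"
    )


def threshold_draws(
    survival_model: VitalRateModel,
    recruitment_model: VitalRateModel,
    P: float,
    n_sim: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """Per-draw lambda_f = 1 thresholds under coefficient uncertainty.

    Draws are multivariate normal around each model's fixed effects,
    independent between the two models; the same seed gives the same draws.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    sb = _draw_betas(survival_model, n_sim, rng)
    rb = _draw_betas(recruitment_model, n_sim, rng)
    d, _ = _solve_thresholds(sb, rb, float(P))
    return d


def confident_threshold(
    survival_model: VitalRateModel,
    recruitment_model: VitalRateModel,
    P: float,
    n_sim: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> float:
    """Disturbance limit below which lambda_f >= 1 with `level` confidence.

    The (1 - level) quantile of the per-draw thresholds; equivalently the
    largest D at which at least `level` of coefficient draws keep the
    population stable or growing.
    """
    draws = threshold_draws(survival_model, recruitment_model, P, n_sim, seed)
    return float(np.quantile(draws, 1.0 - level))


def classify_point(
    survival_model: VitalRateModel,
    recruitment_model: VitalRateModel,
    D: float,
    P: float,
    tol: float = 1e-3,
) -> str:
    """Classify a population's (D, P) against the lambda_f = 1 boundary."""
    lam = _lambda_from_betas(survival_model.beta, recruitment_model.beta, D, P)
    if lam > 1.0 + tol:
        return "increase"
    if lam < 1.0 - tol:
        return "decline"
    return "stable"


def viability_surface(
    survival_model: VitalRateModel,
    recruitment_model: VitalRateModel,
    D_grid: Optional[Sequence[float]] = None,
    P_grid: Optional[Sequence[float]] = None,
    n_sim: int = 10000,
    seed: int = 0,
    populations: Optional[pd.DataFrame] = None,
    level: float = 0.95,
) -> ViabilitySurface:
    """Full (D, P) table of lambda_f plus both threshold curves.

    `populations`, when given, is a frame with columns population, D, P; each
    row is classified as increase / stable / decline relative to the
    point-estimate boundary. One set of coefficient draws (seeded) is shared
    across the whole productivity grid.
    """
    if D_grid is None:
        D_grid = np.round(np.linspace(0.0, 1.0, 101), 10)
    if P_grid is None:
        P_grid = np.round(np.linspace(0.0, 1.0, 101), 10)
    D_grid = np.asarray(D_grid, dtype=float)
    P_grid = np.asarray(P_grid, dtype=float)
    if D_grid.size == 0 or P_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if D_grid.min() < 0 or D_grid.max() > 1 or P_grid.min() < 0 or P_grid.max() > 1:
        raise ValueError("grids must lie within [0, 1]")

    DD, PP = np.meshgrid(D_grid, P_grid, indexing="ij")
    S = predict_rate(survival_model, DD.ravel(), PP.ravel())
    R = predict_rate(recruitment_model, DD.ravel(), PP.ravel())
    table = pd.DataFrame(
        {
            "D": DD.ravel(),
            "P": PP.ravel(),
            "S_f": S,
            "R": R,
            "R_f": recruitment_to_female(R),
            "lambda_f": lambda_f(S, R),
        }
    )

    rng = np.random.default_rng(seed)
    sb = _draw_betas(survival_model, n_sim, rng) if n_sim >= 100 else None
    rb = _draw_betas(recruitment_model, n_sim, rng) if n_sim >= 100 else None
    d_mean = np.empty(P_grid.size)
    d_95 = np.empty(P_grid.size)
    statuses = []
    for i, P in enumerate(P_grid):
        res = mean_threshold(survival_model, recruitment_model, P)
        d_mean[i] = res.d_star
        statuses.append(res.status)
        if sb is None:
            d_95[i] = np.nan
        else:
            draws, _ = _solve_thresholds(sb, rb, float(P))
            d_95[i] = float(np.quantile(draws, 1.0 - level))
    curve = ThresholdCurve(
        P_grid=P_grid,
        D_star_mean=d_mean,
        D_star_95=d_95,
        status_mean=statuses,
        n_sim=n_sim if sb is not None else 0,
        seed=seed,
    )

    classifications = None
    if populations is not None:
        classifications = populations.copy()
        classifications["class"] = [
            classify_point(survival_model, recruitment_model, row.D, row.P)
            for row in populations.itertuples()
        ]
    return ViabilitySurface(table=table, curve=curve, classifications=classifications)
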