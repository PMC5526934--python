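"""Stand development vs forest productivity: the succession analysis.

Quantifies how quickly disturbed boreal stands recover mature-forest
structure as a function of the productivity index P: ordinary least squares
for stand height and (treed-fraction-corrected) canopy cover on
{age, age^2, P, age x P}, and a penalized-spline additive model for the
(vegetation-corrected) deciduous fraction, which is unimodal in stand age
with a peak near 20 years.

Raw inventory covers are diluted by the non-treed / non-vegetated part of a
pixel, so both are rescaled before modelling; pixels without trees or
vegetation are removed, with the removal logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .datatypes import StandPixel
from .errors import FilteredOut, RankDeficiencyError

__all__ = [
    "correct_canopy_cover",
    "correct_deciduous",
    "prepare_pixels",
    "StandStructureFit",
    "DeciduousFit",
    "fit_structure_models",
    "fit_deciduous_model",
    "succession_curves",
]


def correct_canopy_cover(canopy_cover_raw: float, treed_fraction: float) -> float:
    """Canopy cover rescaled to the treed part of the pixel (raw / treed).

    Raises :class:`FilteredOut` for treeless pixels; values above 1 (noise)
    are capped at 1.
    """
    if treed_fraction <= 0.0:
        raise FilteredOut("pixel without trees removed")
    return min(canopy_cover_raw / treed_fraction, 1.0)


def correct_deciduous(deciduous_raw: float, vegetated_fraction: float) -> float:
    """Deciduous fraction rescaled to the vegetated part of the pixel."""
    if vegetated_fraction <= 0.0:
        raise FilteredOut("pixel without vegetation removed")
    return min(deciduous_raw / vegetated_fraction, 1.0)


def prepare_pixels(pixels: Iterable[StandPixel]) -> Tuple[pd.DataFrame, List[Dict]]:
    """Apply both cover corrections; drop (and log) treeless/unvegetated pixels."""
    rows = []
    removed: List[Dict] = []
    for i, px in enumerate(pixels):
        try:
            rows.append(
                {
                    "age": px.age,
                    "height": px.height,
                    "cover": correct_canopy_cover(px.canopy_cover_raw, px.treed_fraction),
                    "deciduous": correct_deciduous(px.deciduous_raw, px.vegetated_fraction),
                    "P": px.P,
                }
            )
        except FilteredOut as exc:
            removed.append({"stage": "succession", "pixel": i, "reason": exc.reason})
    return pd.DataFrame(rows), removed


def _structure_design(age: np.ndarray, P: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(age), age, age**2, P, age * P])


_STRUCTURE_NAMES = ("intercept", "age", "age_sq", "P", "age_x_P")


@dataclass
class StandStructureFit:
    """OLS fits of stand height and corrected canopy cover on age and P."""

    height: sm.regression.linear_model.RegressionResults = field(repr=False)
    cover: sm.regression.linear_model.RegressionResults = field(repr=False)
    names: tuple = _STRUCTURE_NAMES

    def predict_height(self, age, P):
        age, P = np.broadcast_arrays(np.atleast_1d(age).astype(float),
                                     np.atleast_1d(P).astype(float))
        return self.height.predict(_structure_design(age, P))

    def predict_cover(self, age, P):
        age, P = np.broadcast_arrays(np.atleast_1d(age).astype(float),
                                     np.atleast_1d(P).astype(float))
        return self.cover.predict(_structure_design(age, P))


def fit_structure_models(pixels, min_pixels: int = 50) -> StandStructureFit:
    """Least-squares stand-structure models with the age x productivity
    interaction (stand development varies with productivity).

    Accepts StandPixel records or an already-corrected frame from
    :func:`prepare_pixels`.
    """
    frame = pixels if isinstance(pixels, pd.DataFrame) else prepare_pixels(pixels)[0]
    if len(frame) < min_pixels:
        raise FilteredOut(f"only {len(frame)} usable pixels (< {min_pixels})")
    X = _structure_design(frame["age"].to_numpy(), frame["P"].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            "stand-structure design is rank deficient (e.g. all pixels the same age)"
        )
    height = sm.OLS(frame["height"].to_numpy(), X).fit()
    cover = sm.OLS(frame["cover"].to_numpy(), X).fit()
    return StandStructureFit(height=height, cover=cover)


@dataclass
class DeciduousFit:
    """Penalized-spline model of the corrected deciduous fraction."""

    results: object = field(repr=False)
    smoother: BSplines = field(repr=False)
    alpha: float = 0.0
    age_range: Tuple[float, float] = (0.0, 120.0)
    constant: Optional[float] = None  # degenerate zero-variance response

    def predict(self, age, P):
        age, P = np.broadcast_arrays(np.atleast_1d(age).astype(float),
                                     np.atleast_1d(P).astype(float))
        if self.constant is not None:
            return np.full(age.shape, self.constant)
        # the B-spline basis is only defined over the training age span
        age = np.clip(age, *self.age_range)
        exog = np.column_stack([np.ones_like(age), P, age * P])
        basis = self.smoother.transform(age[:, None])
        return self.results.predict(exog, exog_smooth=basis, transform=False)

    def peak_age(self, P: float = 0.5, grid: Optional[np.ndarray] = None) -> float:
        """Stand age at which the fitted deciduous fraction peaks."""
        if grid is None:
            grid = np.linspace(0.0, 80.0, 801)
        pred = self.predict(grid, np.full_like(grid, P))
        return float(grid[int(np.argmax(pred))])


def fit_deciduous_model(
    pixels, min_pixels: int = 100, df: int = 10, alpha_grid: Optional[Sequence[float]] = None
) -> DeciduousFit:
    """Additive model: cubic-spline smooth of age plus a productivity-varying
    level and an age x P interaction, smoothing chosen by GCV.

    The spline basis uses ~`df` cubic B-spline functions; the penalty weight
    is selected by generalized cross-validation over `alpha_grid`
    (log-spaced by default).
    """
    frame = pixels if isinstance(pixels, pd.DataFrame) else prepare_pixels(pixels)[0]
    if len(frame) < min_pixels:
        raise FilteredOut(f"only {len(frame)} usable pixels (< {min_pixels})")
    age = frame["age"].to_numpy()
    if np.unique(age).size < df + 2:
        raise RankDeficiencyError("too few distinct stand ages for the spline basis")
    smoother = BSplines(age[:, None], df=[df], degree=[3], include_intercept=False)
    exog = np.column_stack([np.ones(len(frame)), frame["P"].to_numpy(),
                            age * frame["P"].to_numpy()])
    y = frame["deciduous"].to_numpy()
    if alpha_grid is None:
        alpha_grid = np.logspace(-3, 5, 17)
    if float(np.ptp(y)) < 1e-12:
        # a constant response needs no smooth at all
        return DeciduousFit(
            results=None, smoother=smoother, alpha=float(alpha_grid[-1]),
            age_range=(float(age.min()), float(age.max())), constant=float(y[0]),
        )
    best_alpha, best_gcv, best_res = None, np.inf, None
    for alpha in alpha_grid:
        try:
            res = GLMGam(y, exog=exog, smoother=smoother, alpha=[float(alpha)]).fit()
            gcv = float(res.gcv)
        except Exception:  # e.g. an exact fit at this penalty; try the next one
            continue
        if np.isfinite(gcv) and gcv < best_gcv:
            best_alpha, best_gcv, best_res = float(alpha), gcv, res
    if best_res is None:
        raise RankDeficiencyError("penalized-spline fit failed at every penalty weight")
    return DeciduousFit(
        results=best_res,
        smoother=smoother,
        alpha=best_alpha,
        age_range=(float(age.min()), float(age.max())),
    )


def succession_curves(
    structure: StandStructureFit,
    deciduous: DeciduousFit,
    age_grid: Optional[np.ndarray] = None,
    P_values: Sequence[float] = (0.15, 0.35, 0.55, 0.75),
) -> pd.DataFrame:
    """Predicted height / cover / deciduous curves on an age grid, one set of
    rows per productivity level (the tabular mirror of the succession figure)."""
    if age_grid is None:
        age_grid = np.arange(0.0, 121.0, 5.0)
    age_grid = np.asarray(age_grid, dtype=float)
    frames = []
    for P in P_values:
        Pv = np.full_like(age_grid, float(P))
        frames.append(
            pd.DataFrame(
                {
                    "age": age_grid,
                    "P": Pv,
                    "height": structure.predict_height(age_grid, Pv),
                    "cover": structure.predict_cover(age_grid, Pv),
                    "deciduous": deciduous.predict(age_grid, Pv),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
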