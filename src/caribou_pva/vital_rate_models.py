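"""The two vital-rate models: survival and recruitment vs landscape covariates.

Both are weighted binomial mixed models on the logit scale with a random
intercept per population:

    survival:     logit S = b0 + bD * D     + bP  * P      (weight: n monitored females)
    recruitment:  logit R = b0 + bD * D_lag + bP2 * P^2    (weight: corrected n females)

Productivity enters recruitment squared (the published linearizing
transform) and disturbance enters recruitment lagged by one year.
Coefficient uncertainty is summarised by the observed-information
covariance at the optimum; the parametric bootstrap is the authoritative
interval method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import ranges_by_population
from .errors import (
    BootstrapUnstableError,
    FitFailureError,
    MissingCovariateError,
    SeparationError,
    UncertaintyUnavailableError,
)
from .glmm import fit_weighted_binomial_glmm
from .survey_processing import RecruitmentObservation
from .telemetry_survival import AnnualSurvivalEstimate

__all__ = [
    "VitalRateModel",
    "CoefficientCI",
    "fit_survival_model",
    "fit_recruitment_model",
    "bootstrap_ci",
    "predict_rate",
]


@dataclass
class VitalRateModel:
    """A fitted (or published) vital-rate model on the logit scale."""

    rate: str                      # "survival" | "recruitment"
    beta: np.ndarray               # (3,) fixed effects
    names: tuple
    vcov: Optional[np.ndarray]     # (3, 3) sampling covariance of beta
    sigma_pop: float               # random-intercept SD
    n_obs: int
    link: str = "logit"
    weights_used: bool = True
    data: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.vcov is not None:
            self.vcov = np.asarray(self.vcov, dtype=float)
            if self.vcov.shape != (len(self.beta),) * 2:
                raise ValueError("vcov dimensions do not match beta")
            if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
                raise ValueError("vcov must be symmetric")

    @property
    def se(self) -> np.ndarray:
        if self.vcov is None:
            raise UncertaintyUnavailableError("model carries no covariance matrix")
        return np.sqrt(np.diag(self.vcov))

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> Dict:
        return {
            "rate": self.rate,
            "beta": self.beta.tolist(),
            "names": list(self.names),
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "sigma_pop": self.sigma_pop,
            "n_obs": self.n_obs,
            "link": self.link,
            "weights_used": self.weights_used,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "VitalRateModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            rate=d["rate"],
            beta=np.array(d["beta"]),
            names=tuple(d["names"]),
            vcov=None if d["vcov"] is None else np.array(d["vcov"]),
            sigma_pop=d["sigma_pop"],
            n_obs=d["n_obs"],
            link=d["link"],
            weights_used=d["weights_used"],
        )


@dataclass
class CoefficientCI:
    name: str
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def design_matrix(rate: str, D, P) -> np.ndarray:
    """Fixed-effects design row(s): survival [1, D, P]; recruitment [1, D, P^2]."""
    D = np.atleast_1d(np.asarray(D, dtype=float))
    P = np.atleast_1d(np.asarray(P, dtype=float))
    D, P = np.broadcast_arrays(D, P)
    col = P if rate == "survival" else P**2
    return np.column_stack([np.ones_like(D), D, col])


def _fit(rate, frame, names, nodes, start_beta=None, start_sigma=0.3, compute_vcov=True):
    X = design_matrix(rate, frame["D"].to_numpy(), frame["P"].to_numpy())
    res = fit_weighted_binomial_glmm(
        frame["y"].to_numpy(),
        frame["w"].to_numpy(),
        X,
        frame["population"].to_numpy(),
        nodes=nodes,
        start_beta=start_beta,
        start_sigma=start_sigma,
        compute_vcov=compute_vcov,
    )
    return VitalRateModel(
        rate=rate,
        beta=res.beta,
        names=names,
        vcov=res.vcov_beta if compute_vcov else None,
        sigma_pop=res.sigma,
        n_obs=res.n_obs,
        data=frame,
    )


def fit_survival_model(
    estimates: Sequence[AnnualSurvivalEstimate], ranges, nodes: int = 15
) -> VitalRateModel:
    """Weighted binomial mixed fit of annual survival on D and P.

    Responses are Kaplan-Meier proportions (possibly fractional successes);
    each observation is weighted by the number of monitored females.
    """
    by_pop = ranges_by_population(ranges)
    rows = []
    for est in estimates:
        rg = by_pop.get(est.population)
        if rg is None or est.year not in rg.D_by_year:
            raise MissingCovariateError(
                f"no disturbance value for {est.population} in year {est.year}"
            )
        rows.append(
            {
                "population": est.population,
                "year": est.year,
                "y": est.S_hat,
                "w": float(est.n_females),
                "D": rg.D_by_year[est.year],
                "P": rg.P,
            }
        )
    if len(rows) < 6:
        raise FitFailureError(f"only {len(rows)} survival observations (need >= 6)")
    frame = pd.DataFrame(rows)
    return _fit("survival", frame, ("intercept", "disturbance", "productivity"), nodes)


def fit_recruitment_model(
    observations: Sequence[RecruitmentObservation],
    ranges,
    nodes: int = 15,
    trials: str = "weights",
) -> VitalRateModel:
    """Weighted binomial mixed fit of the calf/female ratio on lagged D and P^2.

    `trials="weights"` (default) treats the ratio as a proportion weighted by
    the corrected female count; `trials="integer"` rounds the corrected
    female count to integer binomial trials.
    """
    by_pop = ranges_by_population(ranges)
    rows = []
    for obs in observations:
        rg = by_pop.get(obs.population)
        if rg is None:
            raise MissingCovariateError(f"unknown population {obs.population}")
        if trials == "integer":
            m = max(1.0, np.round(obs.n_females_corrected))
            y = np.round(obs.R * obs.n_females_corrected) / m
            w = m
        else:
            y, w = obs.R, obs.n_females_corrected
        if not 0.0 <= y <= 1.0:
            raise FitFailureError(
                f"calf/female ratio {y:.3f} outside [0, 1] cannot enter a binomial fit"
            )
        rows.append(
            {
                "population": obs.population,
                "year": obs.year,
                "y": float(y),
                "w": float(w),
                "D": obs.D_lagged,
                "P": rg.P,
            }
        )
    if len(rows) < 6:
        raise FitFailureError(f"only {len(rows)} recruitment observations (need >= 6)")
    frame = pd.DataFrame(rows)
    return _fit("recruitment", frame, ("intercept", "disturbance", "productivity_sq"), nodes)


def predict_rate(model: VitalRateModel, D, P):
    """Fixed-effects prediction (population random intercepts at zero).

    Returns the inverse-logit of the linear predictor; scalar in, scalar out.
    """
    X = design_matrix(model.rate, D, P)
    out = expit(X @ model.beta)
    if np.isscalar(D) and np.isscalar(P):
        return float(out[0])
    return out


def bootstrap_ci(
    model: VitalRateModel,
    data: Optional[pd.DataFrame] = None,
    n_iter: int = 10000,
    seed: int = 0,
    nodes: int = 7,
    max_failure_frac: float = 0.10,
    return_draws: bool = False,
):
    """Parametric-bootstrap percentile intervals for the fixed effects.

    Each iteration simulates responses from the fitted model (new population
    intercepts from Normal(0, sigma_pop^2), binomial responses at the
    rounded observation weights), refits, and collects the coefficients;
    bounds are the 2.5/97.5 percentiles. Raises
    :class:`BootstrapUnstableError` if more than `max_failure_frac` of the
    refits fail.
    """
    frame = data if data is not None else model.data
    if frame is None:
        raise ValueError("bootstrap_ci needs the data that produced the model")
    rng = np.random.default_rng(seed)
    X = design_matrix(model.rate, frame["D"].to_numpy(), frame["P"].to_numpy())
    pops, gidx = np.unique(frame["population"].to_numpy(), return_inverse=True)
    w = frame["w"].to_numpy()
    m = np.maximum(np.round(w), 1.0)
    eta0 = X @ model.beta
    betas = []
    failures = 0
    for _ in range(n_iter):
        u = rng.normal(0.0, model.sigma_pop, len(pops))
        p = expit(eta0 + u[gidx])
        ystar = rng.binomial(m.astype(np.int64), p) / m
        try:
            res = fit_weighted_binomial_glmm(
                ystar, w, X, gidx,
                nodes=nodes,
                start_beta=model.beta,
                start_sigma=max(model.sigma_pop, 0.05),
                compute_vcov=False,
            )
            betas.append(res.beta)
        except (FitFailureError, SeparationError):
            failures += 1
    if failures > max_failure_frac * n_iter:
        raise BootstrapUnstableError(
            f"{failures}/{n_iter} bootstrap refits failed (> {max_failure_frac:.0%})"
        )
    B = np.array(betas)
    out = []
    for j, name in enumerate(model.names):
        lower = float(np.quantile(B[:, j], 0.025, method="lower"))
        upper = float(np.quantile(B[:, j], 0.975, method="higher"))
        out.append(CoefficientCI(name=name, lower=lower, upper=upper))
    if return_draws:
        return out, B
    return out
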