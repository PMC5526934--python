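"""Weighted binomial mixed model with a single random intercept.

Fits logit-link models of the form

    logit p_ij = x_ij' beta + u_j,    u_j ~ Normal(0, sigma^2)

by maximum likelihood, where the response y_ij is a proportion in [0, 1]
carrying a prior weight w_ij. The contribution of one observation to the
conditional log-likelihood is

    w * [ y * log p + (1 - y) * log(1 - p) ],

so integer data with y = successes/trials and w = trials recover the exact
binomial log-likelihood up to an additive constant, while Kaplan-Meier
survival proportions weighted by the number of monitored females are
handled with the same (quasi-likelihood) expression.

The marginal likelihood integrates the random intercept out with adaptive
Gauss-Hermite quadrature centred and scaled at each group's posterior mode
(`nodes=1` is exactly the Laplace approximation). After the quasi-Newton
search the fixed effects are polished by Newton steps on the
quadrature-approximated score, so that with sigma at zero the estimates
coincide with a plain weighted GLM to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp

from .errors import FitFailureError, RankDeficiencyError, SeparationError

__all__ = ["GLMMResult", "fit_weighted_binomial_glmm"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_SIGMA_FLOOR = 1e-8  # below this the model is treated as a fixed-effects GLM
_BETA_BOUND = 30.0   # |beta| beyond this flags (quasi-)separation


@dataclass
class GLMMResult:
    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma: float
    loglik: float
    n_obs: int
    n_groups: int
    nodes: int
    converged: bool
    vcov_full: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))


class _Problem:
    """Data container with the likelihood machinery; rows sorted by group."""

    def __init__(self, y, w, X, groups, nodes):
        y = np.asarray(y, dtype=float)
        w = np.asarray(w, dtype=float)
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        self.y, self.w, self.X = y[order], w[order], X[order]
        _, gidx = np.unique(groups[order], return_inverse=True)
        self.gidx = gidx
        self.G = int(gidx.max()) + 1 if len(gidx) else 0
        # reduceat boundaries (rows are sorted by group)
        self.starts = np.searchsorted(gidx, np.arange(self.G))
        self.n, self.p = self.X.shape
        xk, wk = hermgauss(nodes)
        self.qx, self.logqw = xk, np.log(wk)
        self.nodes = nodes

    # -- conditional log-likelihood pieces ---------------------------------
    def _cond_ll_rows(self, lp):
        """Row-wise w*[y log p + (1-y) log(1-p)] for linear predictor lp."""
        return self.w[..., None] * (
            self.y[..., None] * log_expit(lp) + (1.0 - self.y[..., None]) * log_expit(-lp)
        ) if lp.ndim == 2 else self.w * (
            self.y * log_expit(lp) + (1.0 - self.y) * log_expit(-lp)
        )

    def _modes(self, eta0, sigma):
        """Posterior modes z_g and curvatures of h(z) = -z^2/2 + ll_g(sigma*z)."""
        z = np.zeros(self.G)
        for _ in range(100):
            u = sigma * z[self.gidx]
            p = expit(eta0 + u)
            g1 = np.bincount(self.gidx, weights=self.w * (self.y - p), minlength=self.G)
            h1 = -z + sigma * g1
            curv = np.bincount(self.gidx, weights=self.w * p * (1.0 - p), minlength=self.G)
            h2 = -1.0 - sigma**2 * curv
            step = h1 / h2
            step = np.clip(step, -5.0, 5.0)
            z = z - step
            if np.max(np.abs(h1)) < 1e-11:
                break
        u = sigma * z[self.gidx]
        p = expit(eta0 + u)
        curv = np.bincount(self.gidx, weights=self.w * p * (1.0 - p), minlength=self.G)
        h2 = -1.0 - sigma**2 * curv
        return z, h2

    def _log_integrand(self, eta0, sigma, z_nodes):
        """h(z) = -z^2/2 + sum_i ll_i(sigma * z) at the (G, K) node matrix."""
        lp = eta0[:, None] + sigma * z_nodes[self.gidx]
        rows = self._cond_ll_rows(lp)
        ll_g = np.add.reduceat(rows, self.starts, axis=0)
        return -0.5 * z_nodes**2 + ll_g

    def group_loglik(self, beta, sigma):
        """(G,) vector of marginal log-likelihood contributions."""
        eta0 = self.X @ beta
        if sigma < _SIGMA_FLOOR:
            rows = self._cond_ll_rows(eta0)
            return np.add.reduceat(rows, self.starts)
        z_hat, h2 = self._modes(eta0, sigma)
        s = 1.0 / np.sqrt(-h2)
        z_nodes = z_hat[:, None] + np.sqrt(2.0) * s[:, None] * self.qx[None, :]
        h = self._log_integrand(eta0, sigma, z_nodes)
        return (
            -_LOG_SQRT_2PI
            + 0.5 * np.log(2.0) + np.log(s)
            + logsumexp(self.logqw[None, :] + self.qx[None, :] ** 2 + h, axis=1)
        )

    def nll(self, theta):
        beta, sigma = theta[:-1], theta[-1]
        return -float(np.sum(self.group_loglik(beta, max(sigma, 0.0))))

    # -- score polish ------------------------------------------------------
    def _posterior_node_weights(self, beta, sigma):
        eta0 = self.X @ beta
        z_hat, h2 = self._modes(eta0, sigma)
        s = 1.0 / np.sqrt(-h2)
        z_nodes = z_hat[:, None] + np.sqrt(2.0) * s[:, None] * self.qx[None, :]
        h = self._log_integrand(eta0, sigma, z_nodes)
        logw = self.logqw[None, :] + self.qx[None, :] ** 2 + h
        logw = logw - logsumexp(logw, axis=1, keepdims=True)
        return z_nodes, np.exp(logw)

    def polish_beta(self, beta, sigma, max_iter=15, tol=1e-10):
        """Newton on the quadrature score for beta at fixed sigma.

        The score used is Fisher's identity evaluated with the same adaptive
        quadrature: E_posterior[ sum_i w_i (y_i - p_i(u)) x_i ]. At sigma=0
        this is exactly the weighted-GLM Newton-Raphson.
        """
        beta = beta.copy()
        for _ in range(max_iter):
            if sigma < _SIGMA_FLOOR:
                p = expit(self.X @ beta)
                resid = self.w * (self.y - p)
                fisher_w = self.w * p * (1.0 - p)
            else:
                z_nodes, pw = self._posterior_node_weights(beta, sigma)
                lp = (self.X @ beta)[:, None] + sigma * z_nodes[self.gidx]
                p = expit(lp)
                resid = (pw[self.gidx] * self.w[:, None] * (self.y[:, None] - p)).sum(axis=1)
                fisher_w = (pw[self.gidx] * self.w[:, None] * p * (1.0 - p)).sum(axis=1)
            score = self.X.T @ resid
            if np.max(np.abs(score)) < tol * (1.0 + np.abs(self.w).sum()):
                break
            info = self.X.T @ (fisher_w[:, None] * self.X)
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                break
            step_norm = np.max(np.abs(step))
            if step_norm > 2.0:
                step *= 2.0 / step_norm
            beta = beta + step
        return beta


def _numeric_hessian(fun, x, rel_step=1e-4):
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_weighted_binomial_glmm(
    y: Sequence[float],
    w: Sequence[float],
    X: np.ndarray,
    groups: Sequence,
    nodes: int = 15,
    start_beta: Optional[np.ndarray] = None,
    start_sigma: float = 0.3,
    max_sigma: float = 5.0,
    compute_vcov: bool = True,
) -> GLMMResult:
    """Maximum-likelihood fit of the weighted binomial random-intercept model.

    Parameters
    ----------
    y, w
        Proportion responses in [0, 1] and their prior weights (> 0).
    X
        (n, p) fixed-effects design matrix (include the intercept column).
    groups
        Group (population) labels, one per row.
    nodes
        Adaptive Gauss-Hermite nodes; 1 gives the Laplace approximation.
    start_beta, start_sigma
        Optional warm start (used heavily by the parametric bootstrap).

    Raises
    ------
    RankDeficiencyError, SeparationError, FitFailureError
    """
    prob = _Problem(y, w, X, groups, nodes)
    if prob.n < prob.p + 1:
        raise FitFailureError(f"{prob.n} observations cannot identify {prob.p} coefficients")
    if np.any(prob.w <= 0) or np.any(prob.y < 0) or np.any(prob.y > 1):
        raise FitFailureError("weights must be positive and responses within [0, 1]")
    Xw = prob.X * np.sqrt(prob.w)[:, None]
    if np.linalg.matrix_rank(Xw) < prob.p:
        raise RankDeficiencyError("weighted design matrix is rank deficient")
    ybar = float(np.average(prob.y, weights=prob.w))
    if ybar <= 0.0 or ybar >= 1.0:
        raise SeparationError("response is constant at the boundary; MLE diverges")

    beta0 = np.zeros(prob.p) if start_beta is None else np.asarray(start_beta, dtype=float)
    theta0 = np.append(beta0, min(max(start_sigma, 0.0), max_sigma))
    res = minimize(
        prob.nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * prob.p + [(0.0, max_sigma)],
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500, "maxfun": 5000},
    )
    beta, sigma = res.x[:-1], float(res.x[-1])
    beta = prob.polish_beta(beta, sigma)
    loglik = -prob.nll(np.append(beta, sigma))
    if not np.isfinite(loglik):
        raise FitFailureError(f"non-finite log-likelihood at optimum: {res.message}")
    if np.max(np.abs(beta)) > _BETA_BOUND:
        raise SeparationError(
            f"coefficient magnitude {np.max(np.abs(beta)):.1f} exceeds {_BETA_BOUND}; "
            "quasi-complete separation"
        )
    if not res.success and res.status != 1:  # status 1 = maxiter, tolerable after polish
        raise FitFailureError(f"optimizer failed: {res.message}")

    vcov_beta = np.full((prob.p, prob.p), np.nan)
    vcov_full = None
    if compute_vcov:
        if sigma > 1e-4:
            H = _numeric_hessian(prob.nll, np.append(beta, sigma))
            try:
                vcov_full = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                vcov_full = np.linalg.pinv(H)
            vcov_beta = vcov_full[: prob.p, : prob.p]
        else:
            # sigma estimated at (or next to) the boundary: profile it out
            H = _numeric_hessian(lambda b: prob.nll(np.append(b, sigma)), beta)
            try:
                vcov_beta = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                vcov_beta = np.linalg.pinv(H)
        vcov_beta = 0.5 * (vcov_beta + vcov_beta.T)

    return GLMMResult(
        beta=beta,
        vcov_beta=vcov_beta,
        sigma=sigma,
        loglik=loglik,
        n_obs=prob.n,
        n_groups=prob.G,
        nodes=nodes,
        converged=True,
        vcov_full=vcov_full,
    )
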