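"""Maximum-likelihood mixed models for random-regression reaction norms.

Two model families are supported, both with a population-level random
intercept and (optionally) a correlated random slope over the scaled
temperature covariate, plus an independent random intercept for the
experimental replicate:

* Gaussian, identity link — fitted by minimising the profiled ML deviance:
  for a given relative covariance factor ``Lambda(theta)`` the random-effect
  modes, fixed effects and residual variance have closed forms via a
  penalised least-squares solve, leaving a low-dimensional optimisation over
  ``theta`` only.
* Binomial, logit link — Laplace-approximate marginal likelihood: the joint
  penalised log-likelihood is maximised over the spherical random effects by
  Newton's method (PIRLS) inside an outer quasi-Newton optimisation over the
  fixed effects and ``theta`` jointly.

Parameterisation follows the penalised-spherical-random-effects formulation:
``b = Lambda(theta) u`` with ``u ~ N(0, sigma^2 I)`` (Gaussian) or
``u ~ N(0, I)`` (binomial); ``Lambda`` is block diagonal with one shared
lower-triangular 2x2 block per population (or a scalar if the random slope
is omitted) and a scalar for replicates. ML (not REML) is used throughout so
AIC values are comparable across random-effect structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit, gammaln

__all__ = ["MixedModelResult", "fit_lmm_gaussian", "fit_glmm_binomial"]

_BOUNDARY_TOL = 1e-4


@dataclass
class MixedModelResult:
    """Fitted random-regression mixed model."""

    family: str  # "gaussian" | "binomial"
    random_slope: bool
    beta: np.ndarray  # fixed effects (intercept, slope on scaled temperature)
    cov_beta: np.ndarray
    sd_intercept: float  # population random-intercept SD (response/link scale)
    sd_slope: float  # population random-slope SD (per scaled-temperature unit)
    corr_intercept_slope: float
    sd_replicate: float
    sigma_resid: float | None  # residual SD (Gaussian only)
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    boundary: bool  # a variance component was estimated at (or near) zero
    populations: list = field(repr=False, default_factory=list)
    ranef: pd.DataFrame = field(repr=False, default=None)  # per-population deviations
    ranef_replicate: pd.DataFrame = field(repr=False, default=None)
    theta: np.ndarray = field(repr=False, default=None)

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _design(pop: np.ndarray, t: np.ndarray, rep: np.ndarray | None,
            random_slope: bool):
    """Random-effects design matrix Z and block bookkeeping."""
    pops, pop_idx = np.unique(pop, return_inverse=True)
    n = len(pop)
    per = 2 if random_slope else 1
    q_pop = per * len(pops)
    cols = [q_pop]
    if rep is not None:
        reps, rep_idx = np.unique(rep, return_inverse=True)
        cols.append(len(reps))
    else:
        reps, rep_idx = np.array([]), None
    Z = np.zeros((n, sum(cols)))
    rows = np.arange(n)
    Z[rows, per * pop_idx] = 1.0
    if random_slope:
        Z[rows, per * pop_idx + 1] = t
    if rep is not None:
        Z[rows, q_pop + rep_idx] = 1.0
    return Z, pops, reps, per, q_pop


def _lambda(theta: np.ndarray, n_pop: int, per: int, n_rep: int) -> np.ndarray:
    """Dense block-diagonal relative covariance factor."""
    q = per * n_pop + n_rep
    lam = np.zeros((q, q))
    if per == 2:
        block = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
        k = 3
    else:
        block = np.array([[theta[0]]])
        k = 1
    for g in range(n_pop):
        s = per * g
        lam[s : s + per, s : s + per] = block
    if n_rep:
        for r in range(n_rep):
            lam[per * n_pop + r, per * n_pop + r] = theta[k]
    return lam


def _theta_template(per: int, n_rep: int) -> tuple[np.ndarray, list]:
    if per == 2:
        x0 = [1.0, 0.0, 1.0]
        bounds = [(0.0, None), (None, None), (0.0, None)]
    else:
        x0 = [1.0]
        bounds = [(0.0, None)]
    if n_rep:
        x0.append(0.5)
        bounds.append((0.0, None))
    return np.array(x0), bounds


def fit_lmm_gaussian(
    y: np.ndarray, X: np.ndarray, pop: np.ndarray, t: np.ndarray,
    rep: np.ndarray | None = None, random_slope: bool = True,
    theta_fixed: np.ndarray | None = None,
) -> MixedModelResult:
    """Gaussian linear mixed model by profiled ML.

    Parameters
    ----------
    y, X
        Response and fixed-effects design (first column the intercept).
    pop, t, rep
        Population labels, the scaled-temperature covariate carrying the
        random slope, and optional replicate labels.
    theta_fixed
        Optional relative-covariance parameters to condition on instead of
        optimising (for profiling and for studying the shrinkage of
        conditional modes at known variance parameters).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    Z, pops, reps, per, q_pop = _design(np.asarray(pop), np.asarray(t, float),
                                        None if rep is None else np.asarray(rep),
                                        random_slope)
    q = Z.shape[1]
    n_rep = len(reps)

    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def solve_pls(theta):
        lam = _lambda(theta, len(pops), per, n_rep)
        A = lam.T @ ZtZ @ lam + np.eye(q)
        B = lam.T @ ZtX
        a = lam.T @ Zty
        L = np.linalg.cholesky(A)
        W = solve_triangular(L, B, lower=True)
        w = solve_triangular(L, a, lower=True)
        S = XtX - W.T @ W
        beta = np.linalg.solve(S, Xty - W.T @ w)
        u = solve_triangular(L.T, w - W @ beta, lower=False)
        r2 = max(yty - a @ u - Xty @ beta, 1e-300)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return lam, beta, u, r2, logdet, S

    def deviance(theta):
        try:
            _, _, _, r2, logdet, _ = solve_pls(theta)
        except np.linalg.LinAlgError:
            return 1e12
        return logdet + n * (1.0 + np.log(2.0 * np.pi * r2 / n))

    if theta_fixed is not None:
        theta = np.asarray(theta_fixed, float)
        success = True
    else:
        x0, bounds = _theta_template(per, n_rep)
        res = optimize.minimize(deviance, x0, method="L-BFGS-B", bounds=bounds)
        if not res.success:  # retry from a smaller start
            res2 = optimize.minimize(deviance, 0.2 * x0 + 0.01,
                                     method="Nelder-Mead")
            if res2.fun < res.fun:
                res = res2
        theta = np.asarray(res.x, float)
        success = bool(res.success or res.fun < 1e11)

    lam, beta, u, r2, logdet, S = solve_pls(theta)
    sigma2 = r2 / n
    sigma = float(np.sqrt(sigma2))
    loglik = -0.5 * (logdet + n * (1.0 + np.log(2.0 * np.pi * sigma2)))
    n_theta = len(theta)
    n_params = p + n_theta + 1
    aic = -2.0 * loglik + 2.0 * n_params
    cov_beta = sigma2 * np.linalg.inv(S)

    b = lam @ u  # random-effect deviations on the response scale
    if per == 2:
        T = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
        G = sigma2 * T @ T.T
        sd_int, sd_slo = np.sqrt(np.diag(G))
        corr = float(G[0, 1] / (sd_int * sd_slo)) if sd_int * sd_slo > 0 else 0.0
        ranef = pd.DataFrame({"population": pops,
                              "intercept_dev": b[0:q_pop:2],
                              "slope_dev": b[1:q_pop:2]})
    else:
        sd_int = sigma * theta[0]
        sd_slo, corr = 0.0, 0.0
        ranef = pd.DataFrame({"population": pops,
                              "intercept_dev": b[:q_pop],
                              "slope_dev": np.zeros(len(pops))})
    sd_rep = sigma * theta[-1] if n_rep else 0.0
    ranef_rep = (pd.DataFrame({"replicate": reps, "intercept_dev": b[q_pop:]})
                 if n_rep else pd.DataFrame(columns=["replicate", "intercept_dev"]))

    diag_theta = theta[[0, 2]] if per == 2 else theta[[0]]
    boundary = bool(np.any(diag_theta < _BOUNDARY_TOL))
    return MixedModelResult(
        family="gaussian", random_slope=random_slope, beta=beta,
        cov_beta=cov_beta, sd_intercept=float(sd_int), sd_slope=float(sd_slo),
        corr_intercept_slope=corr, sd_replicate=float(sd_rep),
        sigma_resid=sigma, loglik=float(loglik), aic=float(aic), n_obs=n,
        n_params=n_params, converged=success,
        boundary=boundary, populations=list(pops), ranef=ranef,
        ranef_replicate=ranef_rep, theta=theta,
    )


def fit_glmm_binomial(
    y_success: np.ndarray, n_trials: np.ndarray, X: np.ndarray,
    pop: np.ndarray, t: np.ndarray, rep: np.ndarray | None = None,
    random_slope: bool = True,
) -> MixedModelResult:
    """Binomial-logit GLMM via the Laplace approximation.

    ``y_success`` successes out of ``n_trials`` per row (e.g., germinated of
    viable seeds per dish).
    """
    ys = np.asarray(y_success, float)
    nt = np.asarray(n_trials, float)
    X = np.asarray(X, float)
    n, p = X.shape
    Z, pops, reps, per, q_pop = _design(np.asarray(pop), np.asarray(t, float),
                                        None if rep is None else np.asarray(rep),
                                        random_slope)
    q = Z.shape[1]
    n_rep = len(reps)
    const = float(np.sum(gammaln(nt + 1) - gammaln(ys + 1) - gammaln(nt - ys + 1)))

    def loglik_eta(eta):
        return float(ys @ eta - nt @ np.logaddexp(0.0, eta)) + const

    warm = {"u": np.zeros(q)}

    def laplace_negll(params):
        beta = params[:p]
        theta = params[p:]
        lam = _lambda(theta, len(pops), per, n_rep)
        U = Z @ lam
        off = X @ beta
        u = warm["u"].copy()
        pen = loglik_eta(off + U @ u) - 0.5 * u @ u
        for _ in range(100):
            eta = off + U @ u
            mu = nt * expit(eta)
            g = U.T @ (ys - mu) - u
            if np.max(np.abs(g)) < 1e-9:
                break
            w = nt * expit(eta) * expit(-eta)
            H = U.T @ (U * w[:, None]) + np.eye(q)
            try:
                cf = cho_factor(H)
            except np.linalg.LinAlgError:
                return 1e12
            du = cho_solve(cf, g)
            step = 1.0
            for _ in range(30):  # step halving on the penalised objective
                u_new = u + step * du
                pen_new = loglik_eta(off + U @ u_new) - 0.5 * u_new @ u_new
                if pen_new >= pen - 1e-12:
                    break
                step *= 0.5
            u, pen = u_new, pen_new
        warm["u"] = u
        eta = off + U @ u
        w = nt * expit(eta) * expit(-eta)
        H = U.T @ (U * w[:, None]) + np.eye(q)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e12
        return -(loglik_eta(eta) - 0.5 * u @ u - 0.5 * logdet)

    # starting values: pooled empirical logit for the intercept
    p0 = np.clip(ys.sum() / max(nt.sum(), 1.0), 1e-3, 1 - 1e-3)
    beta0 = np.zeros(p)
    beta0[0] = np.log(p0 / (1 - p0))
    th0, th_bounds = _theta_template(per, n_rep)
    x0 = np.concatenate([beta0, 0.5 * th0])
    bounds = [(None, None)] * p + th_bounds
    res = optimize.minimize(laplace_negll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500})
    if not res.success:
        res2 = optimize.minimize(laplace_negll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "fatol": 1e-8})
        if res2.fun < res.fun:
            res = res2

    beta = np.asarray(res.x[:p], float)
    theta = np.asarray(res.x[p:], float)
    loglik = -float(res.fun)
    n_params = p + len(theta)
    aic = -2.0 * loglik + 2.0 * n_params

    # recover the random-effect modes and conditional information at the optimum
    lam = _lambda(theta, len(pops), per, n_rep)
    laplace_negll(res.x)  # refresh warm-started modes at the optimum
    u = warm["u"]
    U = Z @ lam
    eta = X @ beta + U @ u
    w = nt * expit(eta) * expit(-eta)
    H = U.T @ (U * w[:, None]) + np.eye(q)
    XtWX = X.T @ (X * w[:, None])
    XtWU = X.T @ (U * w[:, None])
    info = XtWX - XtWU @ np.linalg.solve(H, XtWU.T)
    cov_beta = np.linalg.inv(info)

    b = lam @ u
    if per == 2:
        T = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
        G = T @ T.T
        sd_int, sd_slo = np.sqrt(np.diag(G))
        corr = float(G[0, 1] / (sd_int * sd_slo)) if sd_int * sd_slo > 0 else 0.0
        ranef = pd.DataFrame({"population": pops,
                              "intercept_dev": b[0:q_pop:2],
                              "slope_dev": b[1:q_pop:2]})
    else:
        sd_int = theta[0]
        sd_slo, corr = 0.0, 0.0
        ranef = pd.DataFrame({"population": pops,
                              "intercept_dev": b[:q_pop],
                              "slope_dev": np.zeros(len(pops))})
    sd_rep = theta[-1] if n_rep else 0.0
    ranef_rep = (pd.DataFrame({"replicate": reps, "intercept_dev": b[q_pop:]})
                 if n_rep else pd.DataFrame(columns=["replicate", "intercept_dev"]))

    diag_theta = theta[[0, 2]] if per == 2 else theta[[0]]
    boundary = bool(np.any(diag_theta < _BOUNDARY_TOL))
    return MixedModelResult(
        family="binomial", random_slope=random_slope, beta=beta,
        cov_beta=cov_beta, sd_intercept=float(sd_int), sd_slope=float(sd_slo),
        corr_intercept_slope=corr, sd_replicate=float(sd_rep),
        sigma_resid=None, loglik=loglik, aic=float(aic), n_obs=n,
        n_params=n_params, converged=bool(res.success or res.fun < 1e11),
        boundary=boundary, populations=list(pops), ranef=ranef,
        ranef_replicate=ranef_rep, theta=theta,
    )
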