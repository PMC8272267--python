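"""Binomial GLMM with independent random intercepts, fit by Laplace
approximation.

The model is

    y_i ~ Binomial(n_i, p_i),   logit(p_i) = x_i' beta + sum_g z_ig' b_g,
    b_g ~ N(0, sigma_g^2 I)   for each grouping factor g.

Fitting follows the glmer scheme: for fixed variance parameters, penalized
IRLS finds the joint mode of (beta, b); the Laplace-approximate marginal
log-likelihood is profiled over the (few) log-sigma parameters with a
quasi-Newton outer loop.  Fixed-effect standard errors come from the
fixed-effect block of the inverse joint penalized Hessian at the mode,
conditional on the estimated variance components — the same convention as
lme4's glmer (they match glmer to ~3 decimals on shared fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.special import expit

_SIGMA_MIN, _SIGMA_MAX = 1e-6, 50.0  # outer bounds on sigma itself


class GLMMConvergenceError(RuntimeError):
    """Raised when the optimizer fails; carries diagnostics."""


@dataclass
class GLMMResult:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma: dict[str, float]          # random-intercept SDs by factor name
    loglik: float
    n_obs: int
    converged: bool
    random_modes: dict[str, np.ndarray]

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        from scipy.stats import norm
        return 2.0 * norm.sf(np.abs(self.z))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "beta": self.beta,
                             "se": self.se, "z": self.z, "p": self.p})


def _group_matrix(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix((np.ones(n), (np.arange(n), codes)),
                             shape=(n, n_levels))


def fit_binomial_glmm(X: np.ndarray, successes: np.ndarray, trials: np.ndarray,
                      groups: dict[str, np.ndarray],
                      names: list[str] | None = None,
                      maxiter: int = 200) -> GLMMResult:
    """Fit the binomial random-intercept GLMM.

    Parameters
    ----------
    X : (n, p) fixed-effect design (include the intercept column).
    successes, trials : per-row binomial counts.
    groups : mapping factor-name -> integer level codes per row.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(successes, dtype=float)
    n_tr = np.asarray(trials, dtype=float)
    if np.any(n_tr <= 0):
        raise ValueError("all trial counts must be positive")
    if np.any(y < 0) or np.any(y > n_tr):
        raise ValueError("successes must lie in [0, trials]")
    n, p = X.shape
    factor_names = list(groups)
    codes = {g: np.asarray(groups[g], dtype=int) for g in factor_names}
    n_levels = {g: int(codes[g].max()) + 1 for g in factor_names}
    for g in factor_names:
        if n_levels[g] < 2:
            raise ValueError(f"grouping factor {g!r} has a single level; "
                             "random effect is degenerate")
    Z = sparse.hstack([_group_matrix(codes[g], n_levels[g])
                       for g in factor_names]).tocsr()
    q = Z.shape[1]
    sizes = [n_levels[g] for g in factor_names]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    Xd = np.hstack([X, Z.toarray()])  # joint dense design; q is small here
    n_theta = len(factor_names)

    def penalty_diag(sig: np.ndarray) -> np.ndarray:
        d = np.zeros(q)
        for k in range(n_theta):
            d[offsets[k]:offsets[k + 1]] = float(max(sig[k], _SIGMA_MIN)) ** -2
        return d

    def penalized_loglik(eta, b, pen):
        return float(np.sum(y * eta - n_tr * np.logaddexp(0.0, eta))
                     - 0.5 * np.sum(pen * b * b))

    def pirls(sig: np.ndarray, coef0: np.ndarray):
        """Joint (beta, b) mode for fixed variance parameters."""
        pen = penalty_diag(sig)
        pen_full = np.concatenate([np.zeros(p), pen])
        coef = coef0.copy()
        pl_old = -np.inf
        for _ in range(200):
            eta = Xd @ coef
            mu = expit(eta)
            w = np.maximum(n_tr * mu * (1.0 - mu), 1e-12)
            grad = Xd.T @ (y - n_tr * mu) - pen_full * coef
            H = Xd.T @ (Xd * w[:, None])
            H[np.diag_indices_from(H)] += pen_full
            step = np.linalg.solve(H, grad)
            pl_cur = penalized_loglik(eta, coef[p:], pen)
            # damped Newton
            t = 1.0
            for _ in range(40):
                cand = coef + t * step
                if penalized_loglik(Xd @ cand, cand[p:], pen) >= pl_cur:
                    break
                t *= 0.5
            coef = coef + t * step
            pl_new = penalized_loglik(Xd @ coef, coef[p:], pen)
            if abs(pl_new - pl_old) < 1e-12 * (1.0 + abs(pl_new)):
                break
            pl_old = pl_new
        eta = Xd @ coef
        mu = expit(eta)
        w = np.maximum(n_tr * mu * (1.0 - mu), 1e-12)
        Hb = (Z.T @ sparse.diags(w) @ Z).toarray()
        Hb[np.diag_indices_from(Hb)] += pen
        return coef, Hb, pen

    # start: a few IRLS steps of the plain GLM for beta
    beta0 = np.zeros(p)
    for _ in range(8):
        eta = X @ beta0
        mu = expit(eta)
        w = np.maximum(n_tr * mu * (1 - mu), 1e-8)
        zresp = eta + (y - n_tr * mu) / w
        WX = X * w[:, None]
        beta0 = np.linalg.solve(X.T @ WX + 1e-8 * np.eye(p), WX.T @ zresp)
    state = {"coef": np.concatenate([beta0, np.zeros(q)])}

    def neg_marginal(sig: np.ndarray) -> float:
        sig = np.clip(sig, _SIGMA_MIN, _SIGMA_MAX)
        coef, Hb, pen = pirls(sig, state["coef"])
        state["coef"] = coef
        pl = penalized_loglik(Xd @ coef, coef[p:], pen)
        sign, logdet_H = np.linalg.slogdet(Hb)
        if sign <= 0:
            return 1e10
        logdet_pen = float(np.sum(np.log(pen)))
        # Laplace: pl + 0.5 log|pen| - 0.5 log|Hb|
        return -(pl + 0.5 * logdet_pen - 0.5 * logdet_H)

    # finite-difference steps must stay well above the inner-solve noise
    # floor (~1e-9 on the objective), hence the explicit eps values
    res = optimize.minimize(
        neg_marginal, np.full(n_theta, 0.3), method="L-BFGS-B",
        bounds=[(_SIGMA_MIN, _SIGMA_MAX)] * n_theta,
        options={"maxiter": maxiter, "eps": 1e-4})
    if not np.isfinite(res.fun):
        raise GLMMConvergenceError(f"GLMM optimizer failed: {res.message}")

    sig = np.clip(res.x, _SIGMA_MIN, _SIGMA_MAX)
    coef, Hb, pen = pirls(sig, state["coef"])

    def newton_b(beta_v, pen, b0):
        """b-only mode for the joint-outer objective."""
        b = b0.copy()
        eta_fix = X @ beta_v
        pl_old = -np.inf
        for _ in range(100):
            eta = eta_fix + Z @ b
            mu = expit(eta)
            w = np.maximum(n_tr * mu * (1.0 - mu), 1e-12)
            grad = Z.T @ (y - n_tr * mu) - pen * b
            H = (Z.T @ sparse.diags(w) @ Z).toarray()
            H[np.diag_indices_from(H)] += pen
            step = np.linalg.solve(H, grad)
            t = 1.0
            pl_cur = penalized_loglik(eta, b, pen)
            for _ in range(40):
                if penalized_loglik(eta_fix + Z @ (b + t * step),
                                    b + t * step, pen) >= pl_cur:
                    break
                t *= 0.5
            b = b + t * step
            pl_new = penalized_loglik(eta_fix + Z @ b, b, pen)
            if abs(pl_new - pl_old) < 1e-13 * (1.0 + abs(pl_new)):
                break
            pl_old = pl_new
        eta = eta_fix + Z @ b
        mu = expit(eta)
        w = np.maximum(n_tr * mu * (1.0 - mu), 1e-12)
        H = (Z.T @ sparse.diags(w) @ Z).toarray()
        H[np.diag_indices_from(H)] += pen
        return b, H

    # polish: joint outer optimization over (beta, log sigma), matching the
    # glmer convention where beta is an outer parameter under Laplace
    bstate = {"b": coef[p:].copy()}

    def neg_marginal_joint(params: np.ndarray) -> float:
        beta_v = params[:p]
        sv = np.clip(params[p:], _SIGMA_MIN, _SIGMA_MAX)
        pen_v = penalty_diag(sv)
        b, H = newton_b(beta_v, pen_v, bstate["b"])
        bstate["b"] = b
        pl = penalized_loglik(X @ beta_v + Z @ b, b, pen_v)
        sign, logdet_H = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        return -(pl + 0.5 * float(np.sum(np.log(pen_v))) - 0.5 * logdet_H)

    x0 = np.concatenate([coef[:p], sig])
    res2 = optimize.minimize(
        neg_marginal_joint, x0, method="L-BFGS-B",
        bounds=[(None, None)] * p + [(_SIGMA_MIN, _SIGMA_MAX)] * n_theta,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7,
                 "eps": 1e-5})
    if np.isfinite(res2.fun) and res2.fun <= neg_marginal_joint(x0) + 1e-9:
        sig = np.clip(res2.x[p:], _SIGMA_MIN, _SIGMA_MAX)
        pen = penalty_diag(sig)
        b_new, Hb = newton_b(res2.x[:p], pen, bstate["b"])
        coef = np.concatenate([res2.x[:p], b_new])
        res = res2

    beta, b = coef[:p], coef[p:]

    # joint penalized Hessian at the mode; SE(beta) from its inverse
    eta = Xd @ coef
    mu = expit(eta)
    w = np.maximum(n_tr * mu * (1.0 - mu), 1e-12)
    Hj = Xd.T @ (Xd * w[:, None])
    Hj[p:, p:][np.diag_indices(q)] += pen
    cov = np.linalg.inv(Hj)
    se = np.sqrt(np.diag(cov)[:p])

    sigma = {g: (0.0 if sig[k] <= 2 * _SIGMA_MIN else float(sig[k]))
             for k, g in enumerate(factor_names)}
    modes = {g: b[offsets[k]:offsets[k + 1]]
             for k, g in enumerate(factor_names)}
    return GLMMResult(
        names=names or [f"x{j}" for j in range(p)],
        beta=beta, se=se, sigma=sigma, loglik=-float(res.fun),
        n_obs=n, converged=bool(res.success), random_modes=modes)
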