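"""Single-random-intercept mixed models with observation weights.

Two maximum-likelihood fitters used by the seasonal-use and foraging-trend
stages, both supporting per-observation weights (needed for the equal-nest
and equal-day weighting schemes):

* :func:`fit_logistic_mixed` — binomial GLMM, marginal likelihood
  integrated over the random intercept by Gauss–Hermite quadrature;
* :func:`fit_linear_mixed` — Gaussian LMM with marginal covariance
  σ²·diag(1/wᵢ) + τ²·11ᵀ per group, evaluated via the Woodbury identity.

Weights enter as variance weights: observation i contributes its
log-density times wᵢ (logistic) or has residual variance σ²/wᵢ (linear).
Standard errors are Wald, from the numerical Hessian of the marginal
log-likelihood at the optimum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess


@dataclass
class MixedFitResult:
    params: pd.Series  # fixed-effect estimates
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    random_intercept_sd: float
    residual_sd: float | None  # None for the logistic model
    loglike: float
    n_obs: int
    n_groups: int
    converged: bool
    random_effects: pd.Series | None = None  # posterior modes/BLUPs per group
    cov_params: np.ndarray | None = None  # fixed-effect covariance matrix

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


def _prepare(X, y, groups, weights, names):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if weights is None:
        weights = np.ones(len(y))
    weights = np.asarray(weights, float)
    codes, uniq = pd.factorize(np.asarray(groups), sort=True)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, y, weights, codes, list(uniq), list(names)


def fit_logistic_mixed(
    y,
    X,
    groups,
    weights=None,
    names: list[str] | None = None,
    n_quad: int = 25,
    maxiter: int = 500,
) -> MixedFitResult:
    """Weighted logistic regression with a Gaussian random intercept.

    The per-group marginal likelihood ∫ Π σ(ηᵢ+b)^{yᵢwᵢ}(1−σ)^{(1−yᵢ)wᵢ}
    φ(b;0,τ²) db is computed with ``n_quad``-node Gauss–Hermite quadrature;
    (β, log τ) are optimized with BFGS from a GLM start.
    """
    X, y, w, codes, glabels, names = _prepare(X, y, groups, weights, names)
    n_groups = len(glabels)
    nodes, qw = np.polynomial.hermite_e.hermegauss(n_quad)  # probabilists'
    logqw = np.log(qw) - 0.5 * np.log(2 * np.pi)

    def negll(theta):
        beta, log_tau = theta[:-1], theta[-1]
        tau = np.exp(log_tau)
        eta = X @ beta
        # per-observation weighted log-density at each node: (n_obs, n_quad)
        shift = tau * nodes  # (n_quad,)
        lp = eta[:, None] + shift[None, :]
        ll_obs = w[:, None] * (y[:, None] * lp - np.logaddexp(0.0, lp))
        grp_ll = np.zeros((n_groups, n_quad))
        np.add.at(grp_ll, codes, ll_obs)
        return -float(special.logsumexp(grp_ll + logqw[None, :], axis=1).sum())

    import statsmodels.api as sm

    start_glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
    x0 = np.concatenate([start_glm.params, [0.0]])
    res = optimize.minimize(negll, x0, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6})
    if not res.success:  # polish with a derivative-free pass
        res2 = optimize.minimize(
            negll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 5000},
        )
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    H = approx_hess(theta, negll)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        cov_beta = cov[:-1, :-1]
    except np.linalg.LinAlgError:
        se_all = np.full(theta.size, np.nan)
        cov_beta = None
    beta, tau = theta[:-1], float(np.exp(theta[-1]))
    se = se_all[:-1]
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))

    # posterior modes of the random intercepts (for diagnostics/prediction)
    re = np.zeros(n_groups)
    if tau > 1e-8:
        eta = X @ beta
        for g in range(n_groups):
            m = codes == g
            eg, yg, wg = eta[m], y[m], w[m]

            def obj(b, eg=eg, yg=yg, wg=wg):
                lp = eg + b
                return -np.sum(wg * (yg * lp - np.logaddexp(0.0, lp))) + 0.5 * b**2 / tau**2

            re[g] = optimize.minimize_scalar(obj, bounds=(-6 * tau, 6 * tau), method="bounded").x

    idx = pd.Index(names)
    return MixedFitResult(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        zvalues=pd.Series(z, index=idx),
        pvalues=pd.Series(p, index=idx),
        random_intercept_sd=tau,
        residual_sd=None,
        loglike=-res.fun,
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(
            res.success
            or np.max(np.abs(getattr(res, "jac", [np.inf]))) < 1e-3 * (1.0 + abs(res.fun))
        ),
        random_effects=pd.Series(re, index=pd.Index(glabels)),
        cov_params=cov_beta,
    )


def fit_linear_mixed(
    y,
    X,
    groups,
    weights=None,
    names: list[str] | None = None,
) -> MixedFitResult:
    """Weighted Gaussian LMM with one random intercept, fitted by ML.

    For group g with weights w, the marginal covariance is
    V = σ²·diag(1/w) + τ²·11ᵀ; its inverse and determinant come from the
    Woodbury/determinant identities, so each likelihood evaluation is O(n).
    β is profiled out by GLS at each (σ, τ).
    """
    X, y, w, codes, glabels, names = _prepare(X, y, groups, weights, names)
    n, p = X.shape
    n_groups = len(glabels)

    def gls_beta(sig2, tau2):
        # accumulate X'V^{-1}X and X'V^{-1}y over groups via Woodbury
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        quad_resid = 0.0
        for g in range(n_groups):
            m = codes == g
            Xg, yg, wg = X[m], y[m], w[m]
            a = wg / sig2  # diag of D^{-1}
            s = a.sum()
            c = tau2 / (1.0 + tau2 * s)  # Woodbury scalar
            aX = Xg * a[:, None]
            ay = yg * a
            XtVX += Xg.T @ aX - c * np.outer(aX.sum(0), aX.sum(0))
            XtVy += Xg.T @ ay - c * aX.sum(0) * ay.sum()
            logdet += -np.log(a).sum() + np.log1p(tau2 * s)
        beta = np.linalg.solve(XtVX, XtVy)
        for g in range(n_groups):
            m = codes == g
            rg = y[m] - X[m] @ beta
            a = w[m] / sig2
            s = a.sum()
            c = tau2 / (1.0 + tau2 * s)
            ar = rg * a
            quad_resid += rg @ ar - c * ar.sum() ** 2
        return beta, XtVX, logdet, quad_resid

    def negll(theta):
        sig2, tau2 = np.exp(theta)
        try:
            _, _, logdet, quad = gls_beta(sig2, tau2)
        except np.linalg.LinAlgError:
            return 1e10
        return 0.5 * (logdet + quad + n * np.log(2 * np.pi))

    resid_var = max(np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0]), 1e-8)
    x0 = np.log([resid_var, resid_var / 2.0 + 1e-8])
    res = optimize.minimize(negll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    sig2, tau2 = np.exp(res.x)
    beta, XtVX, _, _ = gls_beta(sig2, tau2)
    cov = np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    # Wald test with residual df approximation (n - p); exact small-sample
    # df would need Satterthwaite, which we do not implement
    df = max(n - p, 1)
    pvals = 2 * stats.t.sf(np.abs(t), df)

    # BLUPs
    re = np.zeros(n_groups)
    for g in range(n_groups):
        m = codes == g
        rg = y[m] - X[m] @ beta
        a = w[m] / sig2
        s = a.sum()
        re[g] = tau2 * (rg @ a) / (1.0 + tau2 * s)

    idx = pd.Index(names)
    return MixedFitResult(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        zvalues=pd.Series(t, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        random_intercept_sd=float(np.sqrt(tau2)),
        residual_sd=float(np.sqrt(sig2)),
        loglike=-res.fun,
        n_obs=n,
        n_groups=n_groups,
        converged=bool(res.success),
        random_effects=pd.Series(re, index=pd.Index(glabels)),
        cov_params=cov,
    )
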