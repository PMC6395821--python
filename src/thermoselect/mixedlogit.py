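"""Random-intercept logistic regression by Laplace approximation.

Supports arbitrary (nested or crossed) intercept factors: the nested
"stratum within individual" factor is simply the combined stratum label,
the crossed group factor its own label.  The integrated likelihood over
the random intercepts u ~ N(0, sigma_f^2) per factor is approximated by
Laplace's method at the conditional mode of u, and the approximate
log-likelihood is maximized jointly over the fixed effects and the
variance parameters — the same objective lme4's glmer maximizes at its
default nAGQ = 1.  Dense linear algebra throughout: intended for the
small-to-moderate problems where mixed estimation is requested.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.special import expit


def _one_hot(codes: np.ndarray):
    codes = np.asarray(codes)
    levels, idx = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), idx] = 1.0
    return Z, levels


def _u_mode(y, Xbeta, Z, dpen, u0, max_iter=200, tol=1e-12):
    """Newton maximization of the u-penalized Bernoulli log-likelihood."""
    u = u0.copy()

    def obj(u):
        eta = Xbeta + Z @ u
        return np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * np.sum(dpen * u**2)

    f = obj(u)
    H = None
    for _ in range(max_iter):
        eta = Xbeta + Z @ u
        mu = expit(eta)
        g = Z.T @ (y - mu) - dpen * u
        W = mu * (1 - mu)
        H = (Z * W[:, None]).T @ Z + np.diag(dpen)
        step = np.linalg.solve(H, g)
        t = 1.0
        while t > 1e-10:
            cand = u + t * step
            if obj(cand) >= f - 1e-12:
                break
            t /= 2
        u = u + t * step
        fnew = obj(u)
        if abs(fnew - f) < tol * (abs(f) + 1):
            f = fnew
            break
        f = fnew
    if H is None:
        eta = Xbeta + Z @ u
        mu = expit(eta)
        W = mu * (1 - mu)
        H = (Z * W[:, None]).T @ Z + np.diag(dpen)
    return u, f, H


def laplace_loglike(y, X, Zs, sigmas, beta, u0=None):
    """Laplace-approximate integrated log-likelihood at (beta, sigmas)."""
    y = np.asarray(y, float)
    if not Zs:
        eta = X @ beta
        return float(np.sum(y * eta - np.logaddexp(0.0, eta))), np.zeros(0)
    Z = np.hstack(Zs)
    qs = [Zf.shape[1] for Zf in Zs]
    dpen = np.concatenate(
        [np.full(q, 1.0 / max(s**2, 1e-12)) for q, s in zip(qs, sigmas)]
    )
    u0 = np.zeros(Z.shape[1]) if u0 is None else u0
    u, fmode, H = _u_mode(y, X @ beta, Z, dpen, u0)
    sign, logdet_h = np.linalg.slogdet(H)
    logdet_d = float(np.sum(np.log(dpen)))
    return float(fmode - 0.5 * logdet_h + 0.5 * logdet_d), u


def fit_mixed_logit(y, X, factor_codes: dict, var_floor: float = 1e-6):
    """Fit the random-intercept logistic model.

    Parameters
    ----------
    y, X : response (0/1) and fixed-effects design (with intercept column).
    factor_codes : mapping factor name -> per-row level labels.

    Returns a dict with ``beta``, ``se``, ``sigma2`` (per factor), ``llf``
    (Laplace), ``df`` (fixed params + variance components) and the
    conditional mode ``u``.  Variances estimated below ``var_floor`` are
    reported as exactly 0.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    p = X.shape[1]
    names = list(factor_codes)
    Zs = [_one_hot(factor_codes[n])[0] for n in names]

    start_beta = sm.Logit(y, X).fit(disp=False, method="lbfgs", maxiter=500).params
    x0 = np.concatenate([np.full(len(names), -0.5), start_beta])  # log sigma, beta
    state = {"u": None}

    def neg(par):
        sig = np.exp(par[: len(names)])
        beta = par[len(names) :]
        ll, u = laplace_loglike(y, X, Zs, sig, beta, u0=state["u"])
        state["u"] = u
        return -ll

    res = optimize.minimize(
        neg, x0, method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 4000, "maxfev": 8000},
    )
    sig = np.exp(res.x[: len(names)])
    beta = res.x[len(names) :]
    llf, u = laplace_loglike(y, X, Zs, sig, beta)

    # joint (beta, u) curvature at the optimum for fixed-effect SEs
    if names:
        Z = np.hstack(Zs)
        dpen = np.concatenate(
            [np.full(Zf.shape[1], 1.0 / max(s**2, 1e-12)) for Zf, s in zip(Zs, sig)]
        )
        C = np.hstack([X, Z])
        eta = X @ beta + Z @ u
        mu = expit(eta)
        W = mu * (1 - mu)
        H = (C * W[:, None]).T @ C
        H[p:, p:] += np.diag(dpen)
    else:
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        H = (X * W[:, None]).T @ X
    cov = np.linalg.inv(H)[:p, :p]
    sigma2 = {n: (float(s**2) if s**2 >= var_floor else 0.0) for n, s in zip(names, sig)}
    return {
        "beta": beta,
        "se": np.sqrt(np.diag(cov)),
        "cov": cov,
        "sigma2": sigma2,
        "llf": float(llf),
        "df": p + len(names),
        "u": u,
        "converged": bool(res.success),
    }
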