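"""Blockwise Gaussian marginal maximum likelihood.

Fits linear models ``y = X beta + u_{c(i)} z_i + e_i`` where subjects may
carry a shared random intercept ``u_c ~ N(0, sigma_u^2)`` (``z_i = 1``
for subjects in a cluster, 0 otherwise) and residual variances are
stratified: ``e_i ~ N(0, sigma^2_{strat(i)})``.  This covers the
compound-symmetry random-intercept model, arm-restricted random effects
with per-arm residual variances, and the three-stratum heteroscedastic
models used for actual-group analyses.

The marginal covariance is block diagonal over clusters with blocks
``sigma_u^2 J + diag(d_i)``; the Woodbury identity reduces every
likelihood evaluation to grouped sums (``numpy.bincount``), so an
evaluation is O(n).  ``beta`` is profiled out by GLS; the variance
parameters are optimized on the log scale (floored at ``exp(-30)``,
an effective boundary at zero) by Nelder-Mead with moment-based and
jittered restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG_FLOOR = -30.0
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianMLFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_u2: float
    strata_var: np.ndarray
    loglik: float
    converged: bool
    n_clusters: int


def _suff_stats(lp, y, X, cluster, strat, has_re):
    """Profile loglik pieces for variance parameters ``lp`` (log scale)."""
    if has_re:
        su2 = float(np.exp(np.clip(lp[0], _LOG_FLOOR, 30.0)))
        s2 = np.exp(np.clip(lp[1:], _LOG_FLOOR, 30.0))
    else:
        su2 = 0.0
        s2 = np.exp(np.clip(lp, _LOG_FLOOR, 30.0))
    d = s2[strat]
    w = 1.0 / d
    n, p = X.shape
    in_c = cluster >= 0
    WX = X * w[:, None]
    xtvx = X.T @ WX
    xtvy = WX.T @ y
    logdet = float(np.sum(np.log(d)))
    if has_re and in_c.any():
        cl = cluster[in_c]
        nc = int(cl.max()) + 1
        a = np.bincount(cl, weights=w[in_c], minlength=nc)
        f = su2 / (1.0 + su2 * a)
        sx = np.empty((nc, p))
        for j in range(p):
            sx[:, j] = np.bincount(cl, weights=WX[in_c, j], minlength=nc)
        sy = np.bincount(cl, weights=(w * y)[in_c], minlength=nc)
        xtvx = xtvx - sx.T @ (f[:, None] * sx)
        xtvy = xtvy - sx.T @ (f * sy)
        logdet += float(np.sum(np.log1p(su2 * a)))
    else:
        cl = None
        f = sy = sx = None
    beta = np.linalg.solve(xtvx, xtvy)
    resid = y - X @ beta
    wr = w * resid
    quad = float(resid @ wr)
    if cl is not None:
        sr = np.bincount(cl, weights=wr[in_c], minlength=len(f))
        quad -= float(f @ sr**2)
    ll = -0.5 * (n * _LOG2PI + logdet + quad)
    return ll, beta, xtvx, su2, s2


def _neg_profile_loglik(lp, y, X, cluster, strat, has_re):
    try:
        ll = _suff_stats(lp, y, X, cluster, strat, has_re)[0]
    except np.linalg.LinAlgError:
        return 1e12
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _moment_start(y, X, cluster, strat, n_strata, has_re):
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s2 = np.empty(n_strata)
    for k in range(n_strata):
        rk = resid[strat == k]
        s2[k] = np.var(rk) if rk.size > 1 else np.var(resid)
    s2 = np.clip(s2, 1e-6, None)
    start = list(np.log(s2))
    if has_re:
        in_c = cluster >= 0
        su2 = 1e-3
        if in_c.any():
            cl = cluster[in_c]
            nc = int(cl.max()) + 1
            cnt = np.bincount(cl, minlength=nc)
            keep = cnt > 0
            means = np.bincount(cl, weights=resid[in_c], minlength=nc)[keep]
            means /= cnt[keep]
            within = float(np.mean(s2[strat[in_c]]))
            mbar = float(np.mean(cnt[keep]))
            su2 = max(float(np.var(means)) - within / mbar, 1e-3)
        start = [np.log(su2)] + start
    return np.asarray(start)


def fit_gaussian_ml(
    y,
    X,
    cluster,
    strat,
    n_strata,
    has_re=True,
    n_restarts=2,
    seed=0,
):
    """Maximize the marginal likelihood; return the fitted state.

    Parameters
    ----------
    cluster : int array
        Random-effect cluster index per subject, ``-1`` for subjects whose
        model carries no random term (e.g. the control arm when the random
        effect enters only with treatment).
    strat : int array
        Residual-variance stratum per subject, in ``[0, n_strata)``.
    has_re : bool
        If False no random effect is fitted (``sigma_u^2 = 0``).

    A boundary estimate ``sigma_u^2 -> 0`` is legitimate, not a failure;
    ``converged=False`` marks optimizer failure after all restarts.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cluster = np.asarray(cluster, dtype=int)
    strat = np.asarray(strat, dtype=int)
    args = (y, X, cluster, strat, has_re)

    start = _moment_start(y, X, cluster, strat, n_strata, has_re)
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(n_restarts + 1):
        x0 = start if trial == 0 else start + rng.normal(0, 0.5, size=start.size)
        res = optimize.minimize(
            _neg_profile_loglik,
            x0,
            args=args,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000, "maxfev": 4000},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best.success:
            break
    ll, beta, xtvx, su2, s2 = _suff_stats(best.x, *args)
    cov_beta = np.linalg.inv(xtvx)
    in_c = cluster >= 0
    n_clusters = int(len(np.unique(cluster[in_c]))) if in_c.any() else 0
    n_clusters += int(np.sum(~in_c))
    return GaussianMLFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma_u2=su2 if has_re else 0.0,
        strata_var=np.asarray(s2, dtype=float),
        loglik=float(ll),
        converged=bool(best.success),
        n_clusters=n_clusters,
    )


def loglik_at(params_log, y, X, beta, cluster, strat, has_re=True):
    """Marginal log-likelihood at fixed variance parameters and ``beta``.

    Evaluation helper (and oracle hook): ``params_log`` is the same
    unconstrained vector as used internally, ``beta`` is NOT profiled.
    """
    lp = np.asarray(params_log, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cluster = np.asarray(cluster, dtype=int)
    strat = np.asarray(strat, dtype=int)
    if has_re:
        su2 = float(np.exp(lp[0]))
        s2 = np.exp(lp[1:])
    else:
        su2 = 0.0
        s2 = np.exp(lp)
    resid = y - X @ np.asarray(beta, dtype=float)
    d = s2[strat]
    w = 1.0 / d
    wr = w * resid
    logdet = float(np.sum(np.log(d)))
    quad = float(resid @ wr)
    in_c = cluster >= 0
    if has_re and in_c.any():
        cl = cluster[in_c]
        nc = int(cl.max()) + 1
        a = np.bincount(cl, weights=w[in_c], minlength=nc)
        f = su2 / (1.0 + su2 * a)
        sr = np.bincount(cl, weights=wr[in_c], minlength=nc)
        quad -= float(f @ sr**2)
        logdet += float(np.sum(np.log1p(su2 * a)))
    return -0.5 * (len(y) * _LOG2PI + logdet + quad)
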