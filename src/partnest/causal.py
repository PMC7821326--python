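"""Complier-average-causal-effect (CACE) estimators.

With ``r`` randomization and ``t`` receipt of group treatment (no
always-takers, monotonicity and the exclusion restriction assumed), the
intervention arm reveals compliance while the control arm is a latent
two-component normal mixture of compliers and never-takers.  Estimators:

* two-stage least squares with ``r`` instrumenting ``t`` (IV / IV(Rob));
* the Bloom-type estimator from the linear mixed model
  ``y = alpha + beta_t t + beta_s s + u_AG t + e`` with three residual
  strata and ``s = (1 - t) r``, combined as
  ``(pi_hat beta_t + (1 - pi_hat) beta_s) / pi_hat`` (RE-BLM);
* full-information ML normal mixtures sharing ``pi``, ``gamma`` and the
  component variances across arms, optionally with a complier
  heteroscedasticity term (``sigma_T^2`` replacing ``sigma_C^2`` in the
  intervention arm) and a therapy-group random effect (MM, MM(Het),
  RE-MM, RE-MM(Het), with observed-information or cluster-sandwich SEs).

Component labels cannot switch: membership is anchored by the observed
``t`` in the intervention arm, whose parameters are shared with the
control-arm mixture, and ``pi`` enters both arms' likelihoods jointly.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

from ._ml import fit_gaussian_ml
from .data import TrialDataset
from .results import CaceResult

__all__ = ["fit_iv", "fit_bloom_re", "mixture_loglik", "fit_mixture"]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# instrumental variables (2SLS)
# ---------------------------------------------------------------------------

def fit_iv(data: TrialDataset, robust=False, grouping="actual", covariates=None) -> CaceResult:
    """Two-stage least squares of ``y`` on ``t`` instrumented by ``r``.

    Without covariates the point estimate equals the Wald ratio
    ``(mean_1 - mean_0) / pi_hat``.  ``robust=True`` uses a cluster
    sandwich over the chosen grouping (singletons as own clusters) with a
    ``G/(G-1)`` correction; intervals are Wald z either way.
    """
    r = data.r.astype(float)
    t = data.t.astype(float)
    pi_hat = float(t[r == 1].mean()) if (r == 1).any() else 0.0
    if not (r == 1).any() or not (r == 0).any():
        raise ValueError("both randomization arms are required")
    if pi_hat == 0.0:
        raise ValueError("degenerate first stage: no compliers observed")
    base = data.covariate_matrix(covariates)
    Z = np.column_stack([base, r])
    W = np.column_stack([base, t])
    y = data.y
    n, p = W.shape
    # beta = (W' P_Z W)^{-1} W' P_Z y
    zz_inv = np.linalg.inv(Z.T @ Z)
    WPz = (W.T @ Z) @ zz_inv  # p x q
    A = WPz @ (Z.T @ W)
    beta = np.linalg.solve(A, WPz @ (Z.T @ y))
    resid = y - W @ beta
    A_inv = np.linalg.inv(A)
    if robust:
        codes = data.groups(grouping)
        What = Z @ (zz_inv @ (Z.T @ W))
        G = int(codes.max()) + 1
        scores = np.zeros((G, p))
        for j in range(p):
            scores[:, j] = np.bincount(codes, weights=What[:, j] * resid, minlength=G)
        meat = scores.T @ scores
        cov = G / (G - 1) * A_inv @ meat @ A_inv
        tag = "IV(Rob)"
        n_clusters = G
    else:
        sigma2 = float(resid @ resid) / n
        cov = sigma2 * A_inv
        tag = "IV"
        n_clusters = None
    est = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    q = stats.norm.ppf(0.975)
    names = ["intercept", *list(covariates or ()), "t"]
    return CaceResult(
        method=tag,
        estimate=est,
        se=se,
        ci_low=est - q * se,
        ci_high=est + q * se,
        crit="z",
        fixed_effects=dict(zip(names, map(float, beta))),
        n_obs=n,
        n_clusters=n_clusters,
        compliance_rate=pi_hat,
    )


# ---------------------------------------------------------------------------
# Bloom estimator with random effects
# ---------------------------------------------------------------------------

def fit_bloom_re(data: TrialDataset, covariates=None) -> CaceResult:
    """Random-effects Bloom CACE estimator (RE-BLM).

    Fits ``y = alpha + beta_t t + beta_s s + u_AG t + e`` by Gaussian ML
    with residual strata {control, treated, intervention never-takers}
    and combines ``(pi_hat beta_t + (1 - pi_hat) beta_s) / pi_hat`` with
    ``pi_hat`` the observed intervention-arm compliance.  The SE comes
    from the delta method on ``(beta_t, beta_s)`` (joint ML covariance)
    with ``pi_hat`` treated as an independent binomial proportion.
    """
    s = data.s
    if int(s.sum()) == 0:
        raise ValueError("no never-takers observed: beta_s is not identified")
    base = data.covariate_matrix(covariates)
    X = np.column_stack([base, data.t.astype(float), s.astype(float)])
    codes = data.groups("actual")
    cluster = np.where(data.t == 1, codes, -1)
    strat = np.where(data.r == 0, 0, np.where(data.t == 1, 1, 2))
    fit = fit_gaussian_ml(data.y, X, cluster, strat, n_strata=3)
    beta_t, beta_s = float(fit.beta[-2]), float(fit.beta[-1])
    n1 = int((data.r == 1).sum())
    pi_hat = float(data.t[data.r == 1].mean())
    est = beta_t + (1.0 - pi_hat) / pi_hat * beta_s
    grad = np.array([1.0, (1.0 - pi_hat) / pi_hat])
    cov_b = fit.cov_beta[-2:, -2:]
    var = float(grad @ cov_b @ grad)
    var += (beta_s / pi_hat**2) ** 2 * pi_hat * (1.0 - pi_hat) / n1
    se = float(np.sqrt(var))
    q = stats.norm.ppf(0.975)
    su2 = fit.sigma_u2
    se0, se1, se2 = map(float, fit.strata_var)
    names = ["intercept", *list(covariates or ()), "beta_t", "beta_s"]
    return CaceResult(
        method="RE-BLM",
        estimate=float(est),
        se=se,
        ci_low=float(est - q * se),
        ci_high=float(est + q * se),
        crit="z",
        fixed_effects=dict(zip(names, map(float, fit.beta))),
        variance_components={
            "sigma_u2": su2,
            "sigma_e0_2": se0,
            "sigma_e1_2": se1,
            "sigma_e2_2": se2,
        },
        icc=su2 / (su2 + se1),
        loglik=fit.loglik,
        n_obs=data.n,
        n_clusters=fit.n_clusters,
        converged=fit.converged,
        compliance_rate=pi_hat,
        n_never_takers=int(s.sum()),
    )


# ---------------------------------------------------------------------------
# normal mixture models
# ---------------------------------------------------------------------------

def _mixture_layout(n_cov, het, random_effect):
    """Parameter order: alpha, cov slopes, tau, gamma, logit pi, log variances."""
    names = ["alpha"] + [f"b{j}" for j in range(n_cov)] + ["tau", "gamma", "logit_pi",
                                                           "log_sC2", "log_sN2"]
    if het:
        names.append("log_sT2")
    if random_effect:
        names.append("log_su2")
    return names


_LOG_FLOOR = -30.0  # effective zero for log-variance parameters


def _unpack(params, n_cov, het, random_effect):
    k = 1 + n_cov
    alpha = params[0]
    slopes = params[1:k]
    tau, gamma, lpi = params[k], params[k + 1], params[k + 2]
    logv = np.clip(params[k + 3:], _LOG_FLOOR, 30.0)
    s_c2 = np.exp(logv[0])
    s_n2 = np.exp(logv[1])
    pos = 2
    s_t2 = np.exp(logv[pos]) if het else s_c2
    pos += het
    s_u2 = np.exp(logv[pos]) if random_effect else 0.0
    pi = special.expit(lpi)
    return alpha, slopes, tau, gamma, pi, s_c2, s_n2, s_t2, s_u2


def _mixture_unit_logliks(params, y, xmat, r, t, cluster, het, random_effect):
    """Log-likelihood per independent unit.

    Units in order: treated-complier actual groups (``n_g`` entries),
    intervention-arm never-takers (singletons), control subjects.  The
    total model log-likelihood is the sum.
    """
    n_cov = xmat.shape[1] - 1
    alpha, slopes, tau, gamma, pi, s_c2, s_n2, s_t2, s_u2 = _unpack(
        params, n_cov, het, random_effect
    )
    mu_base = xmat[:, 0] * alpha + (xmat[:, 1:] @ slopes if n_cov else 0.0)

    out = []
    comp = (r == 1) & (t == 1)
    if comp.any():
        resid = y[comp] - mu_base[comp] - tau
        cl = cluster[comp]
        _, cl = np.unique(cl, return_inverse=True)
        nc = int(cl.max()) + 1
        k_c = np.bincount(cl, minlength=nc).astype(float)
        sr = np.bincount(cl, weights=resid, minlength=nc)
        sq = np.bincount(cl, weights=resid**2, minlength=nc)
        a = k_c / s_t2
        f = s_u2 / (1.0 + s_u2 * a)
        quad = sq / s_t2 - f * (sr / s_t2) ** 2
        logdet = k_c * np.log(s_t2) + np.log1p(s_u2 * a)
        ll_c = -0.5 * (k_c * _LOG2PI + logdet + quad) + k_c * np.log(pi)
        out.append(ll_c)
    nev = (r == 1) & (t == 0)
    if nev.any():
        resid = y[nev] - mu_base[nev] - gamma
        ll_n = (
            -0.5 * (_LOG2PI + np.log(s_n2) + resid**2 / s_n2)
            + np.log1p(-pi)
        )
        out.append(ll_n)
    ctrl = r == 0
    if ctrl.any():
        rc = y[ctrl] - mu_base[ctrl]
        log_comp = np.log(pi) - 0.5 * (_LOG2PI + np.log(s_c2) + rc**2 / s_c2)
        log_nev = np.log1p(-pi) - 0.5 * (
            _LOG2PI + np.log(s_n2) + (rc - gamma) ** 2 / s_n2
        )
        out.append(np.logaddexp(log_comp, log_nev))
    return np.concatenate(out) if out else np.zeros(0)


def mixture_loglik(params, data: TrialDataset, het=False, random_effect=False,
                   covariates=None) -> float:
    """Total mixture log-likelihood at an unconstrained parameter vector.

    ``params`` is ``[alpha, covariate slopes..., tau, gamma, logit(pi),
    log(sigma_C^2), log(sigma_N^2), log(sigma_T^2) if het,
    log(sigma_u^2) if random_effect]``.
    """
    params = np.asarray(params, dtype=float)
    if not np.isfinite(params).all():
        raise ValueError("non-finite parameters")
    xmat = data.covariate_matrix(covariates)
    cluster = data.groups("actual")
    return float(
        np.sum(
            _mixture_unit_logliks(
                params, data.y, xmat, data.r, data.t, cluster, het, random_effect
            )
        )
    )


def _mixture_start(data, covariates, het, random_effect):
    xmat = data.covariate_matrix(covariates)
    n_cov = xmat.shape[1] - 1
    y, r, t = data.y, data.r, data.t
    if n_cov:
        coef, *_ = np.linalg.lstsq(xmat, y, rcond=None)
        yr = y - xmat[:, 1:] @ coef[1:]
        slopes = coef[1:]
    else:
        yr = y
        slopes = np.zeros(0)
    pi0 = float(np.clip(t[r == 1].mean(), 0.05, 0.95))
    m_comp = float(yr[(r == 1) & (t == 1)].mean())
    nev_mask = (r == 1) & (t == 0)
    m_nev = float(yr[nev_mask].mean()) if nev_mask.any() else float(yr[r == 0].mean())
    m_ctrl = float(yr[r == 0].mean())
    alpha0 = (m_ctrl - (1.0 - pi0) * m_nev) / pi0
    tau0 = m_comp - alpha0
    gamma0 = m_nev - alpha0
    v_nev = float(yr[nev_mask].var()) if nev_mask.sum() > 1 else 1.0
    v_comp = float(yr[(r == 1) & (t == 1)].var())
    v_ctrl = float(yr[r == 0].var())
    s_c2 = max(v_ctrl - pi0 * (1 - pi0) * gamma0**2, 0.2 * v_ctrl, 1e-3)
    start = [alpha0, *slopes, tau0, gamma0, special.logit(pi0),
             np.log(s_c2), np.log(max(v_nev, 1e-3))]
    if het:
        start.append(np.log(max(v_comp * 0.8, 1e-3)))
    if random_effect:
        cl = data.groups("actual")[(r == 1) & (t == 1)]
        resid = yr[(r == 1) & (t == 1)] - m_comp
        _, cl = np.unique(cl, return_inverse=True)
        cnt = np.bincount(cl)
        means = np.bincount(cl, weights=resid) / cnt
        su0 = max(float(np.var(means)) - v_comp / max(float(cnt.mean()), 1.0), 5e-3)
        start.append(np.log(su0))
    return np.asarray(start, dtype=float)


def fit_mixture(data: TrialDataset, het=False, random_effect=False, robust=False,
                covariates=None, se_method="observed") -> CaceResult:
    """ML fit of the compliance normal-mixture model.

    Parameters
    ----------
    het : bool
        Allow a separate complier variance ``sigma_T^2`` in the
        intervention arm (otherwise ``sigma_C^2`` is shared across arms).
    random_effect : bool
        Include the therapy-group random intercept for treated compliers.
    robust : bool
        Cluster-sandwich SEs over independent units (actual groups and
        singletons) instead of inverse observed information.
    se_method : {"observed", "opg"}
        Non-robust SEs from the observed information (default) or from
        the outer product of unit scores.
    """
    xmat = data.covariate_matrix(covariates)
    cluster = data.groups("actual")
    y, r, t = data.y, data.r, data.t
    if not ((r == 1).any() and (r == 0).any()):
        raise ValueError("both randomization arms are required")
    args = (y, xmat, r, t, cluster, het, random_effect)

    def nll(p):
        ll = np.sum(_mixture_unit_logliks(p, *args))
        return -ll if np.isfinite(ll) else 1e12

    start = _mixture_start(data, covariates, het, random_effect)
    rng = np.random.default_rng(0)
    best = None
    for trial in range(3):
        x0 = start if trial == 0 else start + rng.normal(0, 0.3, size=start.size)
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 6000, "maxfev": 6000},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best.success:
            break
    params = np.clip(best.x, _LOG_FLOOR, None)
    n_cov = xmat.shape[1] - 1
    alpha, slopes, tau, gamma, pi, s_c2, s_n2, s_t2, s_u2 = _unpack(
        params, n_cov, het, random_effect
    )

    # variance parameters pinned to the log floor are boundary estimates
    # (effectively zero); the likelihood is flat there, so inference uses
    # the observed information over the interior parameters only.
    var_pos = np.arange(1 + n_cov + 3, params.size)
    boundary = [j for j in var_pos if params[j] <= _LOG_FLOOR + 10.0]
    free = np.array([j for j in range(params.size) if j not in boundary])

    hess = approx_hess(params, nll)
    h_free = hess[np.ix_(free, free)]
    converged = bool(best.success)
    cov = np.full((params.size, params.size), np.nan)
    try:
        cov[np.ix_(free, free)] = np.linalg.inv(h_free)
        if not np.all(np.linalg.eigvalsh(h_free) > 0):
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    def unit_scores(p, h=1e-5):
        base = _mixture_unit_logliks(p, *args)
        scores = np.empty((base.size, free.size))
        for col, j in enumerate(free):
            hp = p.copy(); hp[j] += h
            hm = p.copy(); hm[j] -= h
            scores[:, col] = (
                _mixture_unit_logliks(hp, *args) - _mixture_unit_logliks(hm, *args)
            ) / (2 * h)
        return scores

    if robust or se_method == "opg":
        scores = unit_scores(params)
        meat = scores.T @ scores
        cov_used = np.full_like(cov, np.nan)
        try:
            if robust:
                g = scores.shape[0]
                bread = np.linalg.inv(h_free)
                cov_used[np.ix_(free, free)] = g / (g - 1) * bread @ meat @ bread
            else:
                cov_used[np.ix_(free, free)] = np.linalg.inv(meat)
        except np.linalg.LinAlgError:
            converged = False
    else:
        cov_used = cov

    idx_tau = 1 + n_cov
    est = float(tau)
    se = float(np.sqrt(cov_used[idx_tau, idx_tau]))
    q = stats.norm.ppf(0.975)

    # control-arm posterior complier probabilities at the MLE
    mu_base = xmat[:, 0] * alpha + (xmat[:, 1:] @ slopes if n_cov else 0.0)
    rc = y[r == 0] - mu_base[r == 0]
    lc = np.log(pi) - 0.5 * (_LOG2PI + np.log(s_c2) + rc**2 / s_c2)
    ln = np.log1p(-pi) - 0.5 * (_LOG2PI + np.log(s_n2) + (rc - gamma) ** 2 / s_n2)
    post = np.exp(lc - np.logaddexp(lc, ln))

    tag = "MM"
    if het:
        tag += "(Het)"
    if random_effect:
        tag = "RE-" + tag
    if robust:
        tag = tag[:-1] + "-Rob)" if tag.endswith(")") else tag + "(Rob)"

    vc = {"sigma_C2": float(s_c2), "sigma_N2": float(s_n2)}
    icc = None
    if het:
        vc["sigma_T2"] = float(s_t2)
    if random_effect:
        vc["sigma_u2"] = float(s_u2)
        icc = float(s_u2 / (s_u2 + s_t2))
    names = _mixture_layout(n_cov, het, random_effect)
    n_units = int(
        len(np.unique(cluster[(r == 1) & (t == 1)]))
        + np.sum((r == 1) & (t == 0))
        + np.sum(r == 0)
    )
    return CaceResult(
        method=tag,
        estimate=est,
        se=se,
        ci_low=float(est - q * se),
        ci_high=float(est + q * se),
        crit="z",
        fixed_effects=dict(zip(names, map(float, params))),
        variance_components=vc,
        icc=icc,
        loglik=float(-best.fun),
        n_obs=data.n,
        n_clusters=n_units,
        converged=converged,
        compliance_rate=float(pi),
        never_taker_offset=float(gamma),
        complier_mean_control=float(alpha),
        complier_mean_intervention=float(alpha + tau),
        n_never_takers=int(data.s.sum()),
        mean_posterior_complier=float(post.mean()),
    )
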