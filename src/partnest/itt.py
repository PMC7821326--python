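"""Intention-to-treat estimators for partially nested trials.

The ITT effect ``delta`` is the coefficient of the randomization
indicator in ``y = alpha + delta * r + e`` (``alpha`` may include
baseline covariates).  Clustering induced by group-administered
treatment is handled either by cluster-robust (sandwich) standard errors
over the intended or actual therapy groups, by GEE with an exchangeable
working correlation, or by Gaussian maximum likelihood with a random
therapy-group intercept — the latter in three flavours: a
compound-symmetry random intercept for every subject (RI), a random
effect restricted to the clustered arm with per-arm residual variances
(RE), and the actual-group model with separate residual variances for
treated compliers and intervention-arm never-takers (RE(Act-Het)).

Every subject outside a therapy group (all controls; noncompliers in an
actual-group analysis) is its own cluster of size one.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._ml import fit_gaussian_ml
from .data import TrialDataset
from .results import FitResult

__all__ = [
    "fit_ols",
    "cluster_robust",
    "fit_gee_exchangeable",
    "fit_random_intercept",
    "fit_re_het",
    "fit_re_act_het",
]


def _design(data: TrialDataset, covariates):
    """Design matrix [1, covariates..., r]; delta is the last coefficient."""
    base = data.covariate_matrix(covariates)
    X = np.column_stack([base, data.r.astype(float)])
    names = ["intercept", *list(covariates or ()), "r"]
    return X, names


def _interval(est, se, crit, df=None):
    q = stats.norm.ppf(0.975) if crit == "z" else stats.t.ppf(0.975, df)
    return est - q * se, est + q * se


def fit_ols(data: TrialDataset, covariates=None) -> FitResult:
    """Ordinary least squares ignoring clustering (method OLS)."""
    X, names = _design(data, covariates)
    res = sm.OLS(data.y, X).fit()
    est, se = res.params[-1], res.bse[-1]
    df = data.n - X.shape[1]
    lo, hi = _interval(est, se, "t", df)
    return FitResult(
        method="OLS",
        estimate=float(est),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        crit="t",
        df=df,
        fixed_effects=dict(zip(names, map(float, res.params))),
        variance_components={"sigma_e2": float(res.scale)},
        loglik=float(res.llf),
        n_obs=data.n,
    )


def cluster_robust(data: TrialDataset, grouping="actual", covariates=None) -> FitResult:
    """OLS point estimate with a cluster sandwich SE (OLS(Rob-Int/Act)).

    The sandwich uses the small-sample multiplier
    ``[G/(G-1)] * [(n-1)/(n-p)]`` and a t interval on ``G - 1`` degrees
    of freedom, ``G`` counting singleton clusters.
    """
    X, names = _design(data, covariates)
    codes = data.groups(grouping)
    n_clusters = int(codes.max()) + 1
    if n_clusters < 2:
        raise ValueError("cluster-robust SE needs at least 2 clusters")
    res = sm.OLS(data.y, X).fit(
        cov_type="cluster",
        cov_kwds={"groups": codes, "use_correction": True},
        use_t=True,
    )
    est, se = res.params[-1], res.bse[-1]
    df = n_clusters - 1
    lo, hi = _interval(est, se, "t", df)
    tag = "OLS(Rob-Act)" if grouping == "actual" else "OLS(Rob-Int)"
    return FitResult(
        method=tag,
        estimate=float(est),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        crit="t",
        df=df,
        fixed_effects=dict(zip(names, map(float, res.params))),
        variance_components={"sigma_e2": float(res.scale)},
        loglik=float(res.llf),
        n_obs=data.n,
        n_clusters=n_clusters,
    )


def fit_gee_exchangeable(data: TrialDataset, grouping="actual", covariates=None) -> FitResult:
    """GEE with exchangeable working correlation and robust SEs (GEE(Int/Act))."""
    X, names = _design(data, covariates)
    codes = data.groups(grouping)
    model = sm.GEE(
        data.y,
        X,
        groups=codes,
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=100)
        except Exception:
            converged = False
            res = model.fit(maxiter=100, start_params=np.zeros(X.shape[1]), first_dep_update=100)
    est, se = res.params[-1], res.bse[-1]
    lo, hi = _interval(est, se, "z")
    alpha = float(np.atleast_1d(model.cov_struct.dep_params)[0])
    tag = "GEE(Act)" if grouping == "actual" else "GEE(Int)"
    return FitResult(
        method=tag,
        estimate=float(est),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        crit="z",
        fixed_effects=dict(zip(names, map(float, res.params))),
        variance_components={"scale": float(res.scale)},
        icc=alpha,
        n_obs=data.n,
        n_clusters=int(codes.max()) + 1,
        converged=converged,
    )


def _ml_fit_result(tag, data, fit, names, icc, extra_vc):
    est = fit.beta[-1]
    se = float(np.sqrt(fit.cov_beta[-1, -1]))
    lo, hi = _interval(est, se, "z")
    return FitResult(
        method=tag,
        estimate=float(est),
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        crit="z",
        fixed_effects=dict(zip(names, map(float, fit.beta))),
        variance_components=extra_vc,
        icc=icc,
        loglik=fit.loglik,
        n_obs=data.n,
        n_clusters=fit.n_clusters,
        converged=fit.converged,
    )


def fit_random_intercept(data: TrialDataset, grouping="actual", covariates=None) -> FitResult:
    """Compound-symmetry random-intercept ML (RI(Int)/RI(Act)).

    Every subject carries the group random intercept, so control-arm
    singletons contribute total variance ``sigma_u^2 + sigma_e^2`` even
    though their between/within split is not identified by the data.
    """
    X, names = _design(data, covariates)
    cluster = data.groups(grouping)
    fit = fit_gaussian_ml(data.y, X, cluster, np.zeros(data.n, int), n_strata=1)
    su2, se2 = fit.sigma_u2, float(fit.strata_var[0])
    tag = "RI(Act)" if grouping == "actual" else "RI(Int)"
    return _ml_fit_result(
        tag, data, fit, names,
        icc=su2 / (su2 + se2),
        extra_vc={"sigma_u2": su2, "sigma_e2": se2},
    )


def fit_re_het(data: TrialDataset, grouping="actual", covariates=None) -> FitResult:
    """Arm-heteroscedastic random-effects ML (RE(Int)/RE(Act)).

    The random therapy-group intercept enters only with ``r`` (intended
    grouping) or only with ``t`` (actual grouping); residual variances
    differ between the control and intervention arms.
    """
    X, names = _design(data, covariates)
    codes = data.groups(grouping)
    carrier = data.r if grouping == "intended" else data.t
    cluster = np.where(carrier == 1, codes, -1)
    strat = data.r.astype(int)
    fit = fit_gaussian_ml(data.y, X, cluster, strat, n_strata=2)
    su2 = fit.sigma_u2
    se0, se1 = map(float, fit.strata_var)
    tag = "RE(Act)" if grouping == "actual" else "RE(Int)"
    return _ml_fit_result(
        tag, data, fit, names,
        icc=su2 / (su2 + se1),
        extra_vc={"sigma_u2": su2, "sigma_e0_2": se0, "sigma_e1_2": se1},
    )


def fit_re_act_het(data: TrialDataset, covariates=None) -> FitResult:
    """Actual-group RE model with complier/never-taker heteroscedasticity.

    Three residual strata — control, treated compliers, intervention-arm
    never-takers — with the random effect on treated compliers only
    (RE(Act-Het)).  Also reports the variance ratio
    ``lambda = (sigma_e1^2 + sigma_u^2) / sigma_e2^2``.  If the
    intervention arm has no never-takers the model is not identified and
    the fit falls back to the two-stratum actual-group model.
    """
    if int(data.s.sum()) == 0:
        warnings.warn(
            "no never-takers in the intervention arm; falling back to RE(Act)",
            stacklevel=2,
        )
        return fit_re_het(data, grouping="actual", covariates=covariates)
    X, names = _design(data, covariates)
    codes = data.groups("actual")
    cluster = np.where(data.t == 1, codes, -1)
    strat = np.where(data.r == 0, 0, np.where(data.t == 1, 1, 2))
    fit = fit_gaussian_ml(data.y, X, cluster, strat, n_strata=3)
    su2 = fit.sigma_u2
    se0, se1, se2 = map(float, fit.strata_var)
    return _ml_fit_result(
        "RE(Act-Het)", data, fit, names,
        icc=su2 / (su2 + se1),
        extra_vc={
            "sigma_u2": su2,
            "sigma_e0_2": se0,
            "sigma_e1_2": se1,
            "sigma_e2_2": se2,
            "lambda": (se1 + su2) / se2,
        },
    )
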