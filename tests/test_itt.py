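"""ITT estimators: point estimates, sandwich SEs, marginal likelihoods."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from partnest import itt
from partnest._ml import loglik_at
from partnest.data import TrialDataset
from partnest.synthetic import ScenarioConfig, generate_trial


def two_arm_frame(y0, y1, groups1=None, t1=None):
    n0, n1 = len(y0), len(y1)
    t1 = [1] * n1 if t1 is None else t1
    groups1 = [f"g{i}" for i in range(n1)] if groups1 is None else groups1
    return TrialDataset(
        pd.DataFrame(
            {
                "id": [f"c{i}" for i in range(n0)] + [f"t{i}" for i in range(n1)],
                "y": list(y0) + list(y1),
                "r": [0] * n0 + [1] * n1,
                "t": [0] * n0 + list(t1),
                "intended_group": [f"c{i}" for i in range(n0)] + list(groups1),
            }
        )
    )


def test_ols_two_arm_difference_in_means():
    d = two_arm_frame([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
    fit = itt.fit_ols(d)
    assert fit.estimate == pytest.approx(1.0)
    assert fit.ci_low <= fit.estimate <= fit.ci_high


def test_every_subject_own_cluster_equals_hc1(midsize_trial):
    """Degenerate clustering: sandwich reduces to HC1 heteroscedastic SE."""
    df = midsize_trial.df.copy()
    df["actual_group"] = df["id"]
    df["t"] = 0
    df.loc[df.r == 0, "t"] = 0
    d = TrialDataset(df.drop(columns=["intended_group", "latent_class"]))
    fit = itt.cluster_robust(d, "actual")
    import statsmodels.api as sm

    X = np.column_stack([np.ones(d.n), d.r])
    hc1 = sm.OLS(d.y, X).fit(cov_type="HC1")
    assert fit.se == pytest.approx(hc1.bse[1], rel=1e-10)


def test_cluster_sandwich_matches_hand_oracle():
    """3 clusters of 2: meat equals sum_g (X_g' e_g)(X_g' e_g)'."""
    y1 = [0.9, 1.4, 0.3, 0.8, 1.1, 0.2]
    d = two_arm_frame([0.1, -0.2, 0.4, 0.0, -0.1, 0.3], y1,
                      groups1=["g1", "g1", "g2", "g2", "g3", "g3"])
    fit = itt.cluster_robust(d, "actual")
    X = np.column_stack([np.ones(d.n), d.r.astype(float)])
    beta = np.linalg.solve(X.T @ X, X.T @ d.y)
    e = d.y - X @ beta
    codes = d.groups("actual")
    meat = np.zeros((2, 2))
    for g in np.unique(codes):
        s = X[codes == g].T @ e[codes == g]
        meat += np.outer(s, s)
    G = codes.max() + 1
    n, p = X.shape
    corr = G / (G - 1) * (n - 1) / (n - p)
    bread = np.linalg.inv(X.T @ X)
    se = np.sqrt(corr * (bread @ meat @ bread)[1, 1])
    assert fit.estimate == pytest.approx(beta[1])
    assert fit.se == pytest.approx(se, rel=1e-12)
    assert fit.df == G - 1


def test_robust_methods_leave_point_estimate_unchanged(midsize_trial):
    base = itt.fit_ols(midsize_trial).estimate
    for grouping in ("intended", "actual"):
        assert itt.cluster_robust(midsize_trial, grouping).estimate == pytest.approx(base)


def test_gee_independence_limit_equals_ols(midsize_trial):
    """With the working correlation pinned at zero GEE is OLS."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones(midsize_trial.n), midsize_trial.r.astype(float)])
    res = sm.GEE(
        midsize_trial.y, X, groups=midsize_trial.groups("actual"),
        cov_struct=sm.cov_struct.Independence(),
    ).fit()
    assert res.params[1] == pytest.approx(itt.fit_ols(midsize_trial).estimate, abs=1e-8)


def test_gee_solves_gls_equations_at_its_working_correlation(midsize_trial):
    """At convergence the GEE estimate equals a direct GLS solve."""
    fit = itt.fit_gee_exchangeable(midsize_trial, "actual")
    alpha = fit.icc
    codes = midsize_trial.groups("actual")
    X = np.column_stack([np.ones(midsize_trial.n), midsize_trial.r.astype(float)])
    y = midsize_trial.y
    xtvx = np.zeros((2, 2))
    xtvy = np.zeros(2)
    for g in np.unique(codes):
        idx = codes == g
        k = idx.sum()
        R = np.full((k, k), alpha) + (1 - alpha) * np.eye(k)
        Ri = np.linalg.inv(R)
        xtvx += X[idx].T @ Ri @ X[idx]
        xtvy += X[idx].T @ Ri @ y[idx]
    beta = np.linalg.solve(xtvx, xtvy)
    assert fit.estimate == pytest.approx(beta[1], abs=1e-6)


@pytest.mark.parametrize("model", ["ri", "re", "re_act_het"])
def test_marginal_loglik_matches_dense_mvn_oracle(model):
    """Blockwise likelihood equals a dense MVN evaluation on 8 subjects."""
    rng = np.random.default_rng(3)
    d = two_arm_frame(
        rng.normal(size=3),
        rng.normal(size=5),
        groups1=["g1", "g1", "g1", "g2", "g2"],
        t1=[1, 1, 0, 1, 0],
    )
    X = np.column_stack([np.ones(8), d.r.astype(float)])
    beta = np.array([0.2, 0.4])
    if model == "ri":
        cluster = d.groups("actual")
        strat = np.zeros(8, int)
        lp = np.log([0.4, 0.9])
        var_by = {0: 0.9, 1: 0.9, 2: 0.9}
        su2 = 0.4
    elif model == "re":
        cluster = np.where(d.t == 1, d.groups("actual"), -1)
        strat = d.r
        lp = np.log([0.4, 0.8, 1.3])
        var_by = {0: 0.8, 1: 1.3, 2: 1.3}
        su2 = 0.4
    else:
        cluster = np.where(d.t == 1, d.groups("actual"), -1)
        strat = np.where(d.r == 0, 0, np.where(d.t == 1, 1, 2))
        lp = np.log([0.4, 0.8, 1.3, 0.6])
        var_by = {0: 0.8, 1: 1.3, 2: 0.6}
        su2 = 0.4
    ll = loglik_at(lp, d.y, X, beta, cluster, strat)
    V = np.diag([var_by[s] for s in strat])
    for c in np.unique(cluster[cluster >= 0]):
        idx = np.where(cluster == c)[0]
        V[np.ix_(idx, idx)] += su2
    oracle = multivariate_normal(mean=X @ beta, cov=V).logpdf(d.y)
    assert ll == pytest.approx(oracle, abs=1e-8)


def test_random_intercept_no_clustering_limit():
    """Zero between-cluster variance: sigma_u2 -> 0 and delta -> OLS."""
    cfg = ScenarioConfig(n_per_arm=2000, group_size=10, compliance_rate=1.0,
                         icc=0.0, seed=21)
    d = generate_trial(cfg)
    fit = itt.fit_random_intercept(d, "actual")
    assert fit.variance_components["sigma_u2"] < 0.04
    assert fit.icc < 0.04
    assert fit.estimate == pytest.approx(itt.fit_ols(d).estimate, abs=0.02)


def test_re_het_homoscedastic_limit():
    cfg = ScenarioConfig(n_per_arm=2000, group_size=5, compliance_rate=0.8,
                         icc=0.05, variance_ratio=1.0, seed=23)
    d = generate_trial(cfg)
    fit = itt.fit_re_het(d, "intended")
    vc = fit.variance_components
    assert vc["sigma_e0_2"] == pytest.approx(vc["sigma_e1_2"], rel=0.15)
    assert fit.converged


def test_re_act_het_recovers_variance_ratio():
    cfg = ScenarioConfig(n_per_arm=5000, group_size=5, compliance_rate=0.8,
                         gamma=0.4, icc=0.05, variance_ratio=1.5, seed=29)
    d = generate_trial(cfg)
    fit = itt.fit_re_act_het(d)
    # gamma != 0 inflates the never-taker residual slightly; wide tolerance
    assert fit.variance_components["lambda"] == pytest.approx(1.5, abs=0.15)


def test_re_act_het_falls_back_without_never_takers():
    cfg = ScenarioConfig(n_per_arm=100, compliance_rate=1.0, seed=31)
    d = generate_trial(cfg)
    with pytest.warns(UserWarning):
        fit = itt.fit_re_act_het(d)
    assert fit.method == "RE(Act)"


def test_covariate_adjustment_changes_se_not_validity(midsize_trial):
    df = midsize_trial.df.copy()
    rng = np.random.default_rng(1)
    df["x"] = 0.5 * df["y"] + rng.normal(size=len(df))
    d = TrialDataset(df)
    fit = itt.fit_ols(d, covariates=["x"])
    assert "x" in fit.fixed_effects
    assert fit.se < itt.fit_ols(d).se  # prognostic covariate tightens the fit
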