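"""CACE estimators: IV, the Bloom random-effects estimator, mixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from partnest import causal, itt
from partnest.causal import _mixture_unit_logliks, mixture_loglik
from partnest.data import TrialDataset
from partnest.synthetic import ScenarioConfig, generate_trial


@pytest.fixture(scope="module")
def noncompliant_trial():
    cfg = ScenarioConfig(
        n_per_arm=300, group_size=5, compliance_rate=0.8, gamma=0.75, tau=0.5,
        icc=0.05, variance_ratio=1.5, seed=7,
    )
    return generate_trial(cfg)


def test_iv_equals_wald_ratio(noncompliant_trial):
    d = noncompliant_trial
    fit = causal.fit_iv(d)
    wald = (d.y[d.r == 1].mean() - d.y[d.r == 0].mean()) / d.t[d.r == 1].mean()
    assert fit.estimate == pytest.approx(wald, rel=1e-10)
    assert fit.compliance_rate == pytest.approx(d.t[d.r == 1].mean())


def test_iv_full_compliance_equals_ols():
    cfg = ScenarioConfig(n_per_arm=150, compliance_rate=1.0, tau=0.4, seed=3)
    d = generate_trial(cfg)
    assert causal.fit_iv(d).estimate == pytest.approx(itt.fit_ols(d).estimate, rel=1e-10)


def test_iv_robust_se_differs_and_is_positive(noncompliant_trial):
    plain = causal.fit_iv(noncompliant_trial)
    rob = causal.fit_iv(noncompliant_trial, robust=True)
    assert rob.estimate == pytest.approx(plain.estimate)
    assert rob.se > 0 and rob.se != pytest.approx(plain.se)


def test_iv_equals_bloom_combination_without_random_effect(noncompliant_trial):
    """OLS fit of the three-group mean model recombines to the Wald IV."""
    d = noncompliant_trial
    X = np.column_stack([np.ones(d.n), d.t.astype(float), d.s.astype(float)])
    beta = np.linalg.lstsq(X, d.y, rcond=None)[0]
    pi_hat = d.t[d.r == 1].mean()
    combo = beta[1] + (1 - pi_hat) / pi_hat * beta[2]
    assert combo == pytest.approx(causal.fit_iv(d).estimate, rel=1e-10)


def test_bloom_re_requires_never_takers():
    cfg = ScenarioConfig(n_per_arm=60, compliance_rate=1.0, seed=2)
    with pytest.raises(ValueError):
        causal.fit_bloom_re(generate_trial(cfg))


def test_bloom_re_recovers_cace_and_icc():
    cfg = ScenarioConfig(n_per_arm=5000, group_size=5, compliance_rate=0.8,
                         gamma=1.0, tau=0.5, icc=0.05, seed=17)
    d = generate_trial(cfg)
    fit = causal.fit_bloom_re(d)
    assert fit.estimate == pytest.approx(0.5, abs=3 * fit.se)
    assert fit.icc == pytest.approx(0.05, abs=0.02)
    assert fit.converged


def test_mixture_cluster_loglik_matches_quadrature_oracle():
    """One cluster of 3 compliers: likelihood equals numeric integration."""
    df = pd.DataFrame(
        {
            "id": ["a", "b", "c", "z"],
            "y": [0.5, 1.2, -0.3, 0.1],
            "r": [1, 1, 1, 0],
            "t": [1, 1, 1, 0],
            "intended_group": ["g1", "g1", "g1", "z"],
        }
    )
    d = TrialDataset(df)
    su2, st2, alpha, tau, gamma, lpi = 0.3, 0.8, 0.2, 0.5, 0.9, 0.4
    params = np.array(
        [alpha, tau, gamma, lpi, np.log(1.0), np.log(1.3), np.log(st2), np.log(su2)]
    )
    ll = _mixture_unit_logliks(
        params, d.y, d.covariate_matrix(None), d.r, d.t, d.groups("actual"),
        het=True, random_effect=True,
    )
    pi = special.expit(lpi)

    def integrand(u):
        return stats.norm.pdf(u, 0, np.sqrt(su2)) * np.prod(
            stats.norm.pdf([0.5, 1.2, -0.3], alpha + tau + u, np.sqrt(st2))
        )

    val, _ = integrate.quad(integrand, -12, 12)
    assert ll[0] == pytest.approx(np.log(val) + 3 * np.log(pi), abs=1e-8)
    # control subject: two-component normal mixture density
    mix = pi * stats.norm.pdf(0.1, alpha, 1.0) + (1 - pi) * stats.norm.pdf(
        0.1, alpha + gamma, np.sqrt(1.3)
    )
    assert ll[1] == pytest.approx(np.log(mix), abs=1e-10)


def test_mixture_model_nesting_identities(noncompliant_trial):
    d = noncompliant_trial
    p_mm = np.array([0.1, 0.4, 0.8, 0.2, np.log(1.0), np.log(1.1)])
    p_het = np.concatenate([p_mm, [np.log(1.0)]])  # sigma_T2 = sigma_C2
    p_re = np.concatenate([p_het, [-30.0]])  # sigma_u2 at the floor
    base = mixture_loglik(p_mm, d)
    assert mixture_loglik(p_het, d, het=True) == pytest.approx(base, abs=1e-8)
    assert mixture_loglik(p_re, d, het=True, random_effect=True) == pytest.approx(
        base, abs=1e-6
    )
    with pytest.raises(ValueError):
        mixture_loglik(np.array([np.nan, 0, 0, 0, 0, 0]), d)


def test_degenerate_control_mixture_independent_of_pi():
    """gamma=0 and sigma_C2=sigma_N2 collapse the control mixture."""
    df = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(6)],
            "y": [0.3, -0.2, 0.8, 0.1, -0.5, 0.9],
            "r": [0] * 6,
            "t": [0] * 6,
            "intended_group": [f"s{i}" for i in range(6)],
        }
    )
    d = TrialDataset(df)
    p1 = np.array([0.1, 0.4, 0.0, special.logit(0.6), np.log(1.2), np.log(1.2)])
    p2 = p1.copy()
    p2[3] = special.logit(0.9)
    assert mixture_loglik(p1, d) == pytest.approx(mixture_loglik(p2, d), abs=1e-10)


def test_fit_mixture_posteriors_and_compliance(noncompliant_trial):
    fit = causal.fit_mixture(noncompliant_trial, het=True, random_effect=True)
    assert fit.converged
    assert 0.0 < fit.compliance_rate < 1.0
    assert 0.0 <= fit.mean_posterior_complier <= 1.0
    # at the MLE the mean control posterior tracks the compliance rate
    assert fit.mean_posterior_complier == pytest.approx(fit.compliance_rate, abs=0.06)
    assert fit.icc is not None and 0 <= fit.icc < 1
    assert fit.method == "RE-MM(Het)"


def test_fit_mixture_robust_and_opg_variants(noncompliant_trial):
    rob = causal.fit_mixture(noncompliant_trial, het=True, robust=True)
    opg = causal.fit_mixture(noncompliant_trial, het=True, se_method="opg")
    obs = causal.fit_mixture(noncompliant_trial, het=True)
    assert rob.method == "MM(Het-Rob)"
    assert rob.estimate == pytest.approx(obs.estimate, abs=1e-6)
    for f in (rob, opg, obs):
        assert f.se > 0
    # same-order standard errors from the three recipes
    assert rob.se == pytest.approx(obs.se, rel=0.5)
    assert opg.se == pytest.approx(obs.se, rel=0.5)


def test_paired_recovery_het_needed_iff_variances_differ():
    """RE-MM(Het) recovers the generating parameters where lam != 1."""
    cfg = ScenarioConfig(n_per_arm=5000, group_size=10, compliance_rate=0.7,
                         gamma=0.75, tau=0.0, icc=0.1, variance_ratio=1.5, seed=101)
    d = generate_trial(cfg)
    het = causal.fit_mixture(d, het=True, random_effect=True)
    assert het.estimate == pytest.approx(0.0, abs=3 * het.se)
    assert het.never_taker_offset == pytest.approx(0.75, abs=0.1)
    assert het.compliance_rate == pytest.approx(0.7, abs=0.02)
    assert het.icc == pytest.approx(0.1, abs=0.04)
    lam_hat = het.variance_components["sigma_T2"] + het.variance_components["sigma_u2"]
    assert lam_hat == pytest.approx(1.5, abs=0.1)
    # the homoscedastic mixture misfits this heteroscedastic truth: its
    # CACE estimate sits further from zero than the het model's
    no_het = causal.fit_mixture(d, random_effect=True)
    assert abs(no_het.estimate) > abs(het.estimate)
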