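"""Monte-Carlo evaluation of the estimators: bias, ICC, coverage, failures.

Two execution paths are provided.

* :func:`run_scenario` / :func:`run_grid` replicate one scenario (or a
  grid of scenarios) through the general fitters in :mod:`partnest.itt`
  and :mod:`partnest.causal`, catching and counting per-method fit
  failures, and summarize bias (against ``pi * tau`` for ITT methods,
  ``tau`` for causal ones), mean ICC and empirical 95%-CI coverage.

* :func:`grid_coverage` is a vectorized closed-form path for the three
  coverage work-horses on the balanced null grid — cluster-robust OLS on
  actual or intended groups, and the arm-heteroscedastic intended-group
  random-effects model, whose ML has an exact solution when all intended
  groups share one size.  It simulates whole replicate blocks as arrays
  and is cross-validated against the general fitters in the test suite.

Replicates use independent substreams spawned from one master seed per
cell, so results are identical regardless of execution order or worker
count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import causal, itt
from .results import ScenarioSummary
from .synthetic import ScenarioConfig, generate_trial

__all__ = ["METHODS", "coverage", "run_scenario", "run_grid", "grid_coverage"]

_Z975 = float(stats.norm.ppf(0.975))

#: method tag -> (fitter, is_causal)
METHODS = {
    "OLS": (lambda d: itt.fit_ols(d), False),
    "OLS(Rob-Int)": (lambda d: itt.cluster_robust(d, "intended"), False),
    "OLS(Rob-Act)": (lambda d: itt.cluster_robust(d, "actual"), False),
    "GEE(Int)": (lambda d: itt.fit_gee_exchangeable(d, "intended"), False),
    "GEE(Act)": (lambda d: itt.fit_gee_exchangeable(d, "actual"), False),
    "RI(Int)": (lambda d: itt.fit_random_intercept(d, "intended"), False),
    "RI(Act)": (lambda d: itt.fit_random_intercept(d, "actual"), False),
    "RE(Int)": (lambda d: itt.fit_re_het(d, "intended"), False),
    "RE(Act)": (lambda d: itt.fit_re_het(d, "actual"), False),
    "RE(Act-Het)": (lambda d: itt.fit_re_act_het(d), False),
    "IV": (lambda d: causal.fit_iv(d), True),
    "IV(Rob)": (lambda d: causal.fit_iv(d, robust=True), True),
    "RE-BLM": (lambda d: causal.fit_bloom_re(d), True),
    "MM": (lambda d: causal.fit_mixture(d), True),
    "MM(Rob)": (lambda d: causal.fit_mixture(d, robust=True), True),
    "MM(Het)": (lambda d: causal.fit_mixture(d, het=True), True),
    "MM(Het-Rob)": (lambda d: causal.fit_mixture(d, het=True, robust=True), True),
    "RE-MM": (lambda d: causal.fit_mixture(d, random_effect=True), True),
    "RE-MM(Het)": (
        lambda d: causal.fit_mixture(d, het=True, random_effect=True),
        True,
    ),
}


def coverage(estimates, ses, crits, truth) -> float:
    """Fraction of intervals ``estimate +/- crit * se`` containing ``truth``."""
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    crits = np.asarray(crits, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates supplied")
    return float(np.mean(np.abs(estimates - truth) <= crits * ses))


def _crit_value(fit):
    return _Z975 if fit.crit == "z" else float(stats.t.ppf(0.975, fit.df))


def run_scenario(config: ScenarioConfig, methods, n_reps, seed=None,
                 extra_methods=None) -> list[ScenarioSummary]:
    """Replicate one scenario and summarize each method.

    ``extra_methods`` maps additional tags to ``(fitter, is_causal)``
    pairs (e.g. stub interval methods in tests).  Failures — exceptions
    or fits flagged unconverged — are excluded from the summaries and
    counted per method.
    """
    registry = dict(METHODS)
    registry.update(extra_methods or {})
    unknown = [m for m in methods if m not in registry]
    if unknown:
        raise ValueError(f"unknown method tags: {unknown}")
    master = config.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n_reps) >> 1
    rows = {m: {"est": [], "se": [], "crit": [], "icc": [], "fail": 0} for m in methods}
    for rep in range(n_reps):
        data = generate_trial(config, seed=int(child_seeds[rep]))
        for m in methods:
            fitter, _ = registry[m]
            try:
                fit = fitter(data)
                if not fit.converged or not np.isfinite(fit.se):
                    raise RuntimeError("fit failed to converge")
            except Exception:
                rows[m]["fail"] += 1
                continue
            rows[m]["est"].append(fit.estimate)
            rows[m]["se"].append(fit.se)
            rows[m]["crit"].append(_crit_value(fit))
            if fit.icc is not None:
                rows[m]["icc"].append(fit.icc)

    scen = {
        "gamma": config.gamma,
        "icc": config.icc,
        "compliance_rate": config.compliance_rate,
        "group_size": config.group_size,
        "variance_ratio": config.variance_ratio,
        "tau": config.tau,
        "n_per_arm": config.n_per_arm,
        "seed": master,
    }
    out = []
    for m in methods:
        _, is_causal = registry[m]
        truth = config.tau if is_causal else config.compliance_rate * config.tau
        est = np.asarray(rows[m]["est"], dtype=float)
        n_ok = est.size
        emp_se = float(est.std(ddof=1)) if n_ok > 1 else float("nan")
        out.append(
            ScenarioSummary(
                method=m,
                n_reps=n_reps,
                n_failed=rows[m]["fail"],
                truth=truth,
                mean_estimate=float(est.mean()) if n_ok else float("nan"),
                bias=float(est.mean() - truth) if n_ok else float("nan"),
                empirical_se=emp_se,
                mc_se=emp_se / np.sqrt(n_ok) if n_ok > 1 else float("nan"),
                mean_icc=(
                    float(np.mean(rows[m]["icc"])) if rows[m]["icc"] else None
                ),
                coverage=(
                    coverage(est, rows[m]["se"], rows[m]["crit"], truth)
                    if n_ok
                    else float("nan")
                ),
                scenario=scen,
            )
        )
    return out


def run_grid(grid, methods, n_reps, seed=0, workers=1) -> pd.DataFrame:
    """One :class:`ScenarioSummary` row per cell x method, stable order.

    Each cell gets an independent seed derived from ``seed`` and its
    position, so the table is identical for any ``workers`` value.
    """
    cell_seeds = [
        int(s) for s in np.random.SeedSequence(seed).generate_state(len(grid)) >> 1
    ]

    def one(i):
        return run_scenario(grid[i], methods, n_reps, seed=cell_seeds[i])

    if workers > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=workers)(delayed(one)(i) for i in range(len(grid)))
    else:
        chunks = [one(i) for i in range(len(grid))]
    records = [s.to_dict() | {"cell": i} for i, cell in enumerate(chunks) for s in cell]
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# vectorized closed-form coverage path (balanced null grid)
# ---------------------------------------------------------------------------

def _simulate_cell_arrays(config: ScenarioConfig, n_reps, rng):
    """Replicate blocks of outcomes for one cell (vectorized).

    Returns control outcomes ``y0`` (reps x n), intervention outcomes
    ``y1``, complier indicators ``comp1`` and the intended-group index of
    each intervention subject.  Same latent-class model as
    :func:`partnest.synthetic.generate_trial`.
    """
    n, m = config.n_per_arm, config.group_size
    pi = config.compliance_rate
    comp0 = rng.random((n_reps, n)) < pi
    y0 = config.mu + np.where(comp0, 0.0, config.gamma) + rng.standard_normal((n_reps, n))
    comp1 = rng.random((n_reps, n)) < pi
    n_groups = -(-n // m)
    gidx = np.repeat(np.arange(n_groups), m)[:n]
    u = rng.standard_normal((n_reps, n_groups)) * np.sqrt(config.sigma_u2)
    e_t = rng.standard_normal((n_reps, n)) * np.sqrt(config.sigma_t2)
    e_n = rng.standard_normal((n_reps, n))
    y1 = config.mu + np.where(
        comp1, config.tau + u[:, gidx] + e_t, config.gamma + e_n
    )
    return y0, y1, comp1, gidx


def _ols_robust_cell(y0, y1, comp1, gidx, grouping):
    """delta-hat, sandwich SE and t df for cluster-robust OLS, per replicate."""
    n_reps, n = y0.shape
    n_groups = int(gidx.max()) + 1
    m = n // n_groups
    if n_groups * m != n:
        raise ValueError("fast path requires equal intended group sizes")
    delta = y1.mean(axis=1) - y0.mean(axis=1)
    e0 = y0 - y0.mean(axis=1, keepdims=True)
    e1 = y1 - y1.mean(axis=1, keepdims=True)
    if grouping == "actual":
        s_comp = (e1 * comp1).reshape(n_reps, n_groups, m).sum(axis=2)
        n_comp = comp1.reshape(n_reps, n_groups, m).sum(axis=2)
        cl_sq = (s_comp**2).sum(axis=1)  # empty groups contribute 0
        nc_sq = ((e1 * ~comp1) ** 2).sum(axis=1)
        m12 = cl_sq + nc_sq
        n_clusters = n + (~comp1).sum(axis=1) + (n_comp > 0).sum(axis=1)
    elif grouping == "intended":
        s_g = e1.reshape(n_reps, n_groups, m).sum(axis=2)
        m12 = (s_g**2).sum(axis=1)
        n_clusters = np.full(n_reps, n + n_groups)
    else:
        raise ValueError("grouping must be 'intended' or 'actual'")
    m11 = (e0**2).sum(axis=1) + m12
    # X = [1, r]: (X'X)^{-1} second row is (-1/n, 2/n)
    a, b = -1.0 / n, 2.0 / n
    var = a * a * m11 + 2 * a * b * m12 + b * b * m12
    corr = n_clusters / (n_clusters - 1) * (2 * n - 1) / (2 * n - 2)
    se = np.sqrt(corr * var)
    df = n_clusters - 1
    return delta, se, df


def _re_int_cell(y0, y1, gidx):
    """Exact balanced-design ML for the intended-group RE model (Wald z).

    With equal group sizes the GLS arm means are the sample means and the
    ML variance components have the one-way ANOVA closed form, truncated
    at the ``sigma_u^2 = 0`` boundary.
    """
    n_reps, n = y0.shape
    n_groups = int(gidx.max()) + 1
    m = n // n_groups
    if n_groups * m != n:
        raise ValueError("fast path requires equal intended group sizes")
    delta = y1.mean(axis=1) - y0.mean(axis=1)
    s0 = y0.var(axis=1)  # ML (divide by n)
    blocks = y1.reshape(n_reps, n_groups, m)
    gmeans = blocks.mean(axis=2)
    ssw = ((blocks - gmeans[:, :, None]) ** 2).sum(axis=(1, 2))
    ssb = m * ((gmeans - y1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    a = ssw / (n - n_groups)  # sigma_e1^2
    b = ssb / n_groups  # sigma_e1^2 + m sigma_u^2
    pooled = (ssw + ssb) / n
    at_boundary = b < a
    b = np.where(at_boundary, pooled, b)
    se = np.sqrt(b / n + s0 / n)
    return delta, se


def grid_coverage(grid, methods, n_reps, seed=0) -> pd.DataFrame:
    """Empirical 95%-CI coverage of the ITT effect per cell x method.

    Vectorized closed-form implementations of ``OLS(Rob-Act)``,
    ``OLS(Rob-Int)`` and ``RE(Int)`` on the balanced grid; all methods
    are evaluated on the same simulated replicates within a cell.
    Returns a tidy frame with one row per cell x method.
    """
    supported = {"OLS(Rob-Act)", "OLS(Rob-Int)", "RE(Int)"}
    bad = set(methods) - supported
    if bad:
        raise ValueError(f"grid_coverage supports {sorted(supported)}, got {sorted(bad)}")
    cell_seeds = np.random.SeedSequence(seed).generate_state(len(grid)) >> 1
    records = []
    for i, config in enumerate(grid):
        rng = np.random.default_rng(int(cell_seeds[i]))
        y0, y1, comp1, gidx = _simulate_cell_arrays(config, n_reps, rng)
        truth = config.compliance_rate * config.tau
        for method in methods:
            if method == "RE(Int)":
                delta, se = _re_int_cell(y0, y1, gidx)
                crit = _Z975
            else:
                grouping = "actual" if method == "OLS(Rob-Act)" else "intended"
                delta, se, df = _ols_robust_cell(y0, y1, comp1, gidx, grouping)
                crit = stats.t.ppf(0.975, df)
            cov = float(np.mean(np.abs(delta - truth) <= crit * se))
            records.append(
                {
                    "cell": i,
                    "method": method,
                    "gamma": config.gamma,
                    "icc": config.icc,
                    "compliance_rate": config.compliance_rate,
                    "group_size": config.group_size,
                    "variance_ratio": config.variance_ratio,
                    "n_reps": n_reps,
                    "coverage": cov,
                    "mean_estimate": float(delta.mean()),
                }
            )
    return pd.DataFrame.from_records(records)
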