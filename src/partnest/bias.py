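"""Closed-form bias approximations for actual-group analyses.

When a partially nested trial is analysed with the *actual* therapy group
(noncompliant subjects as singleton clusters), random-effects and GEE
estimators down-weight clustered compliers by the design effect
``D = 1 + (m - 1) * rho`` while never-takers keep weight one.  If the mean
outcome of never-takers (``mu + gamma``) differs from that of treated
compliers (``mu + tau``), the implied weighted ITT contrast is biased.
The functions here evaluate the resulting first-order approximations for
the weighted ITT effect, the bias of homoscedastic and heteroscedastic
random-effects estimators, and the apparent (inflated) intraclass
correlation.

All functions accept scalars or NumPy arrays (broadcasting applies) and
allow non-integer ``m`` so that a mean observed group size can be used.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "design_effect",
    "itt_weighted",
    "bias_re_act",
    "bias_re_act_het",
    "icc_apparent",
]


def design_effect(m, rho):
    """Design effect ``D = 1 + (m - 1) * rho`` for mean cluster size ``m``.

    Parameters
    ----------
    m : float or array-like
        (Mean) therapy-group size, ``m >= 1``; non-integer values allowed.
    rho : float or array-like
        Intraclass correlation of treated compliers, ``0 <= rho < 1``.
    """
    m = np.asarray(m, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(m < 1):
        raise ValueError("group size m must be >= 1")
    if np.any((rho < 0) | (rho >= 1)):
        raise ValueError("icc rho must lie in [0, 1)")
    out = 1.0 + (m - 1.0) * rho
    return out.item() if out.ndim == 0 else out


def itt_weighted(pi, tau, gamma, m, rho):
    """Approximate weighted ITT effect of an actual-group analysis.

    ``delta_w = (pi*tau + gamma*pi*(1-pi)*(D-1)) / (pi + (1-pi)*D)``.
    Reduces to ``pi*tau`` when ``rho = 0`` (no clustering) and satisfies
    ``itt_weighted - pi*tau == bias_re_act`` identically.
    """
    pi = np.asarray(pi, dtype=float)
    tau = np.asarray(tau, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    d = design_effect(m, rho)
    out = (pi * tau + gamma * pi * (1.0 - pi) * (d - 1.0)) / (pi + (1.0 - pi) * d)
    out = np.asarray(out)
    return out.item() if out.ndim == 0 else out


def bias_re_act(pi, tau, gamma, m, rho):
    """Approximate ITT bias of actual-group RE / GEE estimators.

    ``(gamma - tau) * pi * (1 - pi) * (D - 1) / (pi + (1 - pi) * D)``:
    linear in ``gamma - tau``, zero at ``gamma == tau``, increasing in the
    design effect ``D``.
    """
    pi = np.asarray(pi, dtype=float)
    diff = np.asarray(gamma, dtype=float) - np.asarray(tau, dtype=float)
    d = design_effect(m, rho)
    out = diff * pi * (1.0 - pi) * (d - 1.0) / (pi + (1.0 - pi) * d)
    out = np.asarray(out)
    return out.item() if out.ndim == 0 else out


def bias_re_act_het(pi, tau, gamma, m, rho, lam):
    """Bias approximation for the heteroscedastic actual-group RE model.

    Same form as :func:`bias_re_act` with ``D`` replaced by ``lam * D``
    where ``lam`` is the complier/never-taker variance ratio; the sign
    reverses when ``lam < 1/D``.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("variance ratio lam must be positive")
    pi = np.asarray(pi, dtype=float)
    diff = np.asarray(gamma, dtype=float) - np.asarray(tau, dtype=float)
    ld = lam * design_effect(m, rho)
    out = diff * pi * (1.0 - pi) * (ld - 1.0) / (pi + (1.0 - pi) * ld)
    out = np.asarray(out)
    return out.item() if out.ndim == 0 else out


def icc_apparent(pi, tau, gamma, m, rho, lam=1.0, variant="squared"):
    """Apparent ICC of an actual-group random-effects analysis.

    The between-group variance is estimated about the intervention-arm
    mean, so it absorbs the squared gap between the complier mean and the
    arm mean whenever ``gamma != tau``.  With

    ``Q = (gamma - tau)**2 * (1 - pi) * D / (pi + (1 - pi) * D)**2``

    the apparent ICC is ``(rho + Q) / (1 + Q)``, which exceeds ``rho``
    (quadratically in ``gamma - tau``) except at ``gamma == tau``.

    Parameters
    ----------
    variant : {"squared", "as_printed"}
        "squared" (default) uses the squared mean difference; "as_printed"
        uses the first power, provided for comparison only.
    lam : float
        Replaces ``D`` by ``lam * D`` for the heteroscedastic model;
        defaults to 1 (homoscedastic).
    """
    if variant not in ("squared", "as_printed"):
        raise ValueError("variant must be 'squared' or 'as_printed'")
    pi = np.asarray(pi, dtype=float)
    rho = np.asarray(rho, dtype=float)
    diff = np.asarray(gamma, dtype=float) - np.asarray(tau, dtype=float)
    d = np.asarray(lam, dtype=float) * design_effect(m, rho)
    num = diff**2 if variant == "squared" else diff
    q = num * (1.0 - pi) * d / (pi + (1.0 - pi) * d) ** 2
    out = (rho + q) / (1.0 + q)
    out = np.asarray(out)
    return out.item() if out.ndim == 0 else out
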