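"""Simulation of partially nested trials under latent compliance classes.

The data-generating model has two latent classes, compliers and
never-takers, drawn i.i.d. Bernoulli(``pi``) in both arms:

* never-taker, either arm:        ``y = mu + gamma + eN``, ``eN ~ N(0, sigma_N^2)``
* complier, control arm:          ``y = mu + eC``,         ``eC ~ N(0, sigma_C^2)``
* complier, group-therapy arm:    ``y = mu + tau + u_AG + eT``,
  ``eT ~ N(0, sigma_T^2)``, shared group effect ``u_AG ~ N(0, sigma_u^2)``.

Variances are parameterized through the intraclass correlation ``rho``
and the variance ratio ``lam``: ``sigma_u^2 = rho * lam`` and
``sigma_T^2 = (1 - rho) * lam``, with ``sigma_N^2 = sigma_C^2 = 1``, so
the total complier variance in the intervention arm is ``lam`` and the
ICC among treated compliers is ``rho``.

Intended therapy groups fill sequentially in randomization order in
blocks of ``group_size``; the actual group replaces the group label by
the subject id for noncompliers, so actual groups are nested in intended
groups, singleton compliers remain clusters of size 1, and fully
noncompliant intended groups vanish as clusters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import TrialDataset, derive_actual_groups

__all__ = [
    "ScenarioConfig",
    "generate_trial",
    "assign_actual_groups",
    "build_scenario_grid",
    "study_grid",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation cell.

    Attributes
    ----------
    n_per_arm : int
        Subjects randomized to each arm.
    group_size : int
        Intended therapy-group size ``m``; the last group may be smaller
        when ``n_per_arm`` is not a multiple of ``m``.
    compliance_rate : float
        Bernoulli compliance probability ``pi`` in (0, 1].
    mu : float
        Mean outcome of compliers in the control arm.
    tau : float
        Complier average causal effect; the ITT effect is ``pi * tau``.
    gamma : float
        Mean offset of never-takers relative to control compliers.
    icc : float
        Intraclass correlation ``rho`` among treated compliers, in [0, 1).
    variance_ratio : float
        ``lam``: total complier variance in the intervention arm relative
        to the (unit) never-taker variance.
    seed : int
        Default RNG seed for this cell.
    """

    n_per_arm: int = 200
    group_size: int = 5
    compliance_rate: float = 0.8
    mu: float = 0.0
    tau: float = 0.0
    gamma: float = 0.0
    icc: float = 0.05
    variance_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 1 or self.group_size < 1:
            raise ValueError("n_per_arm and group_size must be positive")
        if not (0.0 < self.compliance_rate <= 1.0):
            raise ValueError("compliance_rate must lie in (0, 1]")
        if not (0.0 <= self.icc < 1.0):
            raise ValueError("icc must lie in [0, 1)")
        if self.variance_ratio <= 0:
            raise ValueError("variance_ratio must be positive")
        for name in ("mu", "tau", "gamma", "icc", "variance_ratio", "compliance_rate"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def sigma_u2(self) -> float:
        return self.icc * self.variance_ratio

    @property
    def sigma_t2(self) -> float:
        return (1.0 - self.icc) * self.variance_ratio

    sigma_n2 = 1.0
    sigma_c2 = 1.0


def generate_trial(config: ScenarioConfig, seed: int | None = None) -> TrialDataset:
    """Draw one complete trial dataset under the latent-class model.

    Latent class is retained in a ``latent_class`` column for
    simulation-only oracle checks; estimators never read it.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_per_arm
    m = config.group_size
    pi = config.compliance_rate

    # control arm: latent compliers ~ N(mu, 1), never-takers ~ N(mu+gamma, 1)
    comp0 = rng.random(n) < pi
    y0 = config.mu + np.where(comp0, 0.0, config.gamma) + rng.standard_normal(n)

    # intervention arm: sequential intended groups of size m
    comp1 = rng.random(n) < pi
    n_groups = math.ceil(n / m)
    gidx = np.repeat(np.arange(n_groups), m)[:n]
    u = rng.standard_normal(n_groups) * math.sqrt(config.sigma_u2)
    e_t = rng.standard_normal(n) * math.sqrt(config.sigma_t2)
    e_n = rng.standard_normal(n)
    y1 = config.mu + np.where(
        comp1, config.tau + u[gidx] + e_t, config.gamma + e_n
    )

    width = len(str(n))
    ids0 = [f"C{i + 1:0{width}d}" for i in range(n)]
    ids1 = [f"T{i + 1:0{width}d}" for i in range(n)]
    ig1 = [f"G{g + 1:03d}" for g in gidx]

    df = pd.DataFrame(
        {
            "id": ids0 + ids1,
            "y": np.concatenate([y0, y1]),
            "r": [0] * n + [1] * n,
            "t": np.concatenate([np.zeros(n, int), comp1.astype(int)]),
            "intended_group": ids0 + ig1,
            "latent_class": np.where(
                np.concatenate([comp0, comp1]), "complier", "never_taker"
            ),
        }
    )
    df["actual_group"] = derive_actual_groups(df)
    return TrialDataset(df)


def assign_actual_groups(dataset: TrialDataset) -> TrialDataset:
    """(Re)construct ``actual_group`` from ``intended_group`` and ``t``."""
    df = dataset.df.copy()
    df["actual_group"] = derive_actual_groups(df)
    return TrialDataset(df)


_FACTOR_FIELDS = {
    "gamma": "gamma",
    "icc": "icc",
    "rho": "icc",
    "compliance_rate": "compliance_rate",
    "pi": "compliance_rate",
    "group_size": "group_size",
    "m": "group_size",
    "variance_ratio": "variance_ratio",
    "lam": "variance_ratio",
    "lambda": "variance_ratio",
    "tau": "tau",
    "mu": "mu",
    "n_per_arm": "n_per_arm",
}

#: canonical iteration order of grid factors (outermost first)
_FACTOR_ORDER = (
    "gamma",
    "icc",
    "compliance_rate",
    "group_size",
    "variance_ratio",
    "tau",
    "mu",
    "n_per_arm",
)


def build_scenario_grid(factors: dict, base: ScenarioConfig | None = None):
    """Cartesian product of factor levels as a list of :class:`ScenarioConfig`.

    Factor names accept field names or the symbols ``rho``, ``pi``, ``m``,
    ``lam``/``lambda``.  Ordering is deterministic (canonical field order,
    levels in the order given) and each cell receives ``seed = base.seed +
    cell_index`` so replicate streams never collide across cells.
    """
    base = base or ScenarioConfig()
    mapped: dict[str, list] = {}
    for name, levels in factors.items():
        if name not in _FACTOR_FIELDS:
            raise ValueError(f"unknown factor {name!r}")
        levels = list(levels)
        if not levels:
            raise ValueError(f"factor {name!r} has no levels")
        mapped[_FACTOR_FIELDS[name]] = levels
    names = [f for f in _FACTOR_ORDER if f in mapped]
    configs = []
    for i, combo in enumerate(itertools.product(*(mapped[f] for f in names))):
        configs.append(
            replace(base, seed=base.seed + i, **dict(zip(names, combo)))
        )
    return configs


def study_grid(base: ScenarioConfig | None = None):
    """The full 216-cell null-effect factorial of the simulation study.

    ``gamma`` from -1 to 1 in steps of 0.25, ``rho`` in {0.05, 0.1},
    ``pi`` in {0.7, 0.8}, ``m`` in {5, 10}, ``lam`` in {2/3, 1, 3/2},
    ``tau = 0``, 200 subjects per arm.
    """
    return build_scenario_grid(
        {
            "gamma": [round(-1 + 0.25 * k, 2) for k in range(9)],
            "rho": [0.05, 0.1],
            "pi": [0.7, 0.8],
            "m": [5, 10],
            "lam": [2 / 3, 1.0, 3 / 2],
        },
        base=base or ScenarioConfig(n_per_arm=200, tau=0.0),
    )
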