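"""Result containers for model fits and Monte-Carlo summaries."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import math


@dataclass
class FitResult:
    """Treatment-effect estimate from one method on one dataset.

    ``crit`` records the reference distribution of the interval:
    ``"z"`` for Wald intervals from ML / GEE fits, ``"t"`` with ``df``
    degrees of freedom for OLS and cluster-robust OLS.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    crit: str = "z"
    df: float | None = None
    fixed_effects: dict = field(default_factory=dict)
    variance_components: dict = field(default_factory=dict)
    icc: float | None = None
    loglik: float | None = None
    n_obs: int = 0
    n_clusters: int | None = None
    converged: bool = True

    def __post_init__(self):
        if self.converged and not (self.se > 0 or math.isnan(self.se)):
            raise ValueError("converged fit must have positive SE")

    @property
    def z(self) -> float:
        return self.estimate / self.se

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CaceResult(FitResult):
    """Complier-average-causal-effect estimate with mixture diagnostics."""

    compliance_rate: float | None = None
    never_taker_offset: float | None = None
    complier_mean_control: float | None = None
    complier_mean_intervention: float | None = None
    n_never_takers: int | None = None
    mean_posterior_complier: float | None = None


@dataclass
class ScenarioSummary:
    """Monte-Carlo summary for one scenario x method."""

    method: str
    n_reps: int
    n_failed: int
    truth: float
    mean_estimate: float
    bias: float
    empirical_se: float
    mc_se: float
    mean_icc: float | None
    coverage: float
    scenario: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        scen = d.pop("scenario")
        for k, v in scen.items():
            d[f"scenario_{k}"] = v
        return d
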