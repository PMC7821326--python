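"""Subject-level trial data container and validation.

A :class:`TrialDataset` holds one row per subject of a partially nested
trial: a continuous outcome ``y``, the randomization indicator ``r``
(1 = group-therapy arm), the treatment-receipt indicator ``t``, the
intended therapy group ``intended_group`` (unique per control subject),
the actual group ``actual_group`` (unique for everyone who did not
receive group treatment), and an optional baseline covariate ``x``.
Simulated data may also carry the latent compliance class, which exists
purely for oracle checks — no estimator reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("id", "y", "r", "t")
OPTIONAL_COLUMNS = ("intended_group", "actual_group", "latent_class", "x")


class TrialDataError(ValueError):
    """Raised when subject-level data violate the design invariants."""


def derive_actual_groups(df: pd.DataFrame) -> pd.Series:
    """Actual group: the intended group for treated subjects, own id otherwise.

    Noncompliant intervention subjects and all control subjects become
    singleton clusters identified by their own subject id; a lone complier
    keeps its intended-group label as a cluster of size 1, and intended
    groups whose members are all noncompliant vanish as clusters.
    """
    if "intended_group" not in df.columns:
        raise TrialDataError("intended_group is required to derive actual_group")
    t = df["t"].to_numpy()
    ig = df["intended_group"].astype(object)
    if ig[t == 1].isna().any():
        rows = df.index[(t == 1) & ig.isna()].tolist()[:5]
        raise TrialDataError(f"treated subject with missing intended_group at rows {rows}")
    return ig.where(t == 1, df["id"].astype(object))


@dataclass
class TrialDataset:
    """Validated subject-level data for a partially nested trial."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TrialDataError(f"missing required columns: {missing}")
        df = df.copy()
        df["r"] = df["r"].astype(int)
        df["t"] = df["t"].astype(int)
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()[:5]
            raise TrialDataError(f"duplicate subject ids: {dupes}")
        if not df["r"].isin((0, 1)).all() or not df["t"].isin((0, 1)).all():
            raise TrialDataError("r and t must be binary 0/1")
        bad = df.index[(df["r"] == 0) & (df["t"] == 1)]
        if len(bad):
            raise TrialDataError(
                f"control subjects received treatment (no always-takers "
                f"supported) at rows {bad.tolist()[:5]}"
            )
        if not np.isfinite(df["y"].to_numpy(dtype=float)).all():
            raise TrialDataError("non-finite outcome values")
        if "intended_group" in df.columns:
            # control subjects are their own intended "group"; a missing
            # label for an intervention subject stays missing (an intended
            # analysis then fails loudly rather than lumping subjects)
            ig = df["intended_group"].astype(object)
            df["intended_group"] = ig.where(df["r"] == 1, df["id"].astype(object))
        if "actual_group" not in df.columns and "intended_group" in df.columns:
            df["actual_group"] = derive_actual_groups(df)
        if "actual_group" in df.columns:
            ag = df["actual_group"].astype(object)
            df["actual_group"] = ag.where(df["t"] == 1, df["id"].astype(object))
            missing = df["actual_group"].isna()
            if missing.any():
                raise TrialDataError(
                    f"treated subjects without an actual group at rows "
                    f"{df.index[missing].tolist()[:5]}"
                )
            if "intended_group" in df.columns:
                treated = df["t"] == 1
                nested = (
                    df.loc[treated, "actual_group"]
                    == df.loc[treated, "intended_group"]
                )
                if not nested.all():
                    raise TrialDataError(
                        "actual groups must be nested in intended groups"
                    )
        self.df = df.reset_index(drop=True)

    # -- column accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=float)

    @property
    def r(self) -> np.ndarray:
        return self.df["r"].to_numpy(dtype=int)

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy(dtype=int)

    @property
    def s(self) -> np.ndarray:
        """Observed never-taker indicator, ``s = (1 - t) * r``."""
        return (1 - self.t) * self.r

    @property
    def x(self) -> np.ndarray | None:
        if "x" not in self.df.columns:
            return None
        return self.df["x"].to_numpy(dtype=float)

    def groups(self, grouping: str) -> np.ndarray:
        """Integer-coded cluster labels for 'intended' or 'actual' grouping."""
        col = {"intended": "intended_group", "actual": "actual_group"}.get(grouping)
        if col is None:
            raise ValueError("grouping must be 'intended' or 'actual'")
        if col not in self.df.columns:
            raise TrialDataError(f"{col} column is required for this analysis")
        labels = self.df[col]
        if labels.isna().any():
            raise TrialDataError(f"missing {col} labels: cannot form clusters")
        codes, _ = pd.factorize(labels)
        return codes

    def covariate_matrix(self, covariates) -> np.ndarray:
        """Design matrix [1, covariates...] for the requested column names."""
        cols = [np.ones(self.n)]
        for name in covariates or ():
            if name not in self.df.columns:
                raise TrialDataError(f"unknown covariate column {name!r}")
            cols.append(self.df[name].to_numpy(dtype=float))
        return np.column_stack(cols)
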