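"""Reading trial data, scenario configuration, and writing results.

The canonical subject-level CSV schema is::

    id, y, r, t, intended_group, actual_group, latent_class, x

with ``actual_group``, ``latent_class`` and ``x`` optional;
``actual_group`` is reconstructed from ``intended_group`` and ``t`` when
absent.  A column-mapping option accommodates files with other headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .data import TrialDataset, TrialDataError
from .results import CaceResult, FitResult, ScenarioSummary
from .synthetic import ScenarioConfig, build_scenario_grid

SCHEMA_VERSION = 1

__all__ = ["read_trial_csv", "write_trial_csv", "read_grid_config",
           "write_results", "read_results"]


def read_trial_csv(path, column_map=None) -> TrialDataset:
    """Load and validate a subject-level CSV.

    Parameters
    ----------
    column_map : dict, optional
        Mapping from canonical names (``id``, ``y``, ``r``, ``t``, ...)
        to the column names actually present in the file.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    try:
        return TrialDataset(df)
    except TrialDataError as exc:
        raise TrialDataError(f"{path}: {exc}") from exc


def write_trial_csv(dataset: TrialDataset, path) -> None:
    dataset.df.to_csv(path, index=False)


def read_grid_config(path, base: ScenarioConfig | None = None):
    """Scenario grid from a YAML/JSON mapping of factor name -> levels.

    Top-level keys: ``factors`` (required) and ``base`` (optional
    overrides of :class:`ScenarioConfig` defaults).
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "factors" not in cfg:
        raise ValueError(f"{path}: expected a mapping with a 'factors' key")
    base_kwargs = cfg.get("base", {})
    base = base or ScenarioConfig(**base_kwargs)
    return build_scenario_grid(cfg["factors"], base=base)


_RESULT_TYPES = {
    "FitResult": FitResult,
    "CaceResult": CaceResult,
    "ScenarioSummary": ScenarioSummary,
}


def write_results(results, path, format=None) -> None:
    """Serialize FitResult / CaceResult / ScenarioSummary lists losslessly.

    ``format`` is inferred from the file suffix when omitted (``.json``
    or ``.csv``).  JSON preserves nested mappings exactly; CSV flattens
    scenario fields with a ``scenario_`` prefix.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    records = []
    for res in results:
        rec = res.to_dict()
        rec["_type"] = type(res).__name__
        rec["_schema_version"] = SCHEMA_VERSION
        records.append(rec)
    if fmt == "json":
        path.write_text(json.dumps(records, indent=2, default=float))
    elif fmt == "csv":
        flat = []
        for rec in records:
            row = {}
            for key, val in rec.items():
                if isinstance(val, dict):
                    for k2, v2 in val.items():
                        row[f"{key}.{k2}"] = v2
                else:
                    row[key] = val
            flat.append(row)
        pd.DataFrame.from_records(flat).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported result format {fmt!r}")


def read_results(path):
    """Inverse of :func:`write_results` for the JSON format."""
    records = json.loads(Path(path).read_text())
    out = []
    for rec in records:
        cls = _RESULT_TYPES[rec.pop("_type")]
        rec.pop("_schema_version", None)
        if cls is ScenarioSummary:
            scen = {
                k.removeprefix("scenario_"): rec.pop(k)
                for k in list(rec)
                if k.startswith("scenario_")
            }
            rec["scenario"] = scen
        out.append(cls(**rec))
    return out
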