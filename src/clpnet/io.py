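"""CSV dialects for panel data and YAML (de)serialization of configs.

Two on-disk dialects:

* wide — one row per participant x wave, one column per variable
  (the in-memory layout of :class:`~clpnet.cohort.PanelDataset`);
* long — one row per participant x wave x variable with columns
  participant_id, wave, variable, value, group, age, gender, instrument.

Writes are canonical (sorted rows, fixed column order, shortest
round-tripping float representation) so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    LATENT_COLUMNS,
    OBSERVED_VARIABLES,
    AttritionModel,
    GeneratorConfig,
    MeasurementModel,
    PanelDataset,
    TrueNetwork,
)

__all__ = [
    "write_panel_csv",
    "read_panel_table",
    "generator_config_to_dict",
    "generator_config_from_dict",
    "save_config_yaml",
    "load_config_yaml",
]

_META = ["participant_id", "wave", "group", "age", "gender", "instrument"]
_VALUE_VARS = list(OBSERVED_VARIABLES) + list(LATENT_COLUMNS)


def _canonical_wide(table: pd.DataFrame) -> pd.DataFrame:
    cols = _META + [c for c in _VALUE_VARS if c in table.columns]
    out = table[cols].sort_values(["participant_id", "wave"], kind="mergesort")
    return out.reset_index(drop=True)


def write_panel_csv(data: PanelDataset, path, dialect: str = "wide") -> None:
    wide = _canonical_wide(data.table)
    if dialect == "wide":
        wide.to_csv(path, index=False)
    elif dialect == "long":
        value_cols = [c for c in _VALUE_VARS if c in wide.columns]
        long = wide.melt(id_vars=_META, value_vars=value_cols,
                         var_name="variable", value_name="value")
        long["variable"] = pd.Categorical(long["variable"], categories=value_cols)
        long = long.sort_values(["participant_id", "wave", "variable"],
                                kind="mergesort").reset_index(drop=True)
        long["variable"] = long["variable"].astype(str)
        long = long[["participant_id", "wave", "variable", "value",
                     "group", "age", "gender", "instrument"]]
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_panel_table(path, dialect: str = "wide") -> PanelDataset:
    """Read and validate a panel CSV in either dialect."""
    # round_trip parsing so write -> read -> write is byte-identical
    raw = pd.read_csv(path, float_precision="round_trip")
    if dialect == "wide":
        missing = [c for c in _META if c not in raw.columns]
        if missing:
            raise ValueError(f"wide panel file missing columns: {missing}")
        dup = raw.duplicated(subset=["participant_id", "wave"])
        if dup.any():
            lines = (raw.index[dup] + 2).tolist()  # 1-based incl. header
            raise ValueError(f"duplicate (participant, wave) rows at lines {lines}")
        return PanelDataset(_canonical_wide(raw))
    if dialect == "long":
        need = ["participant_id", "wave", "variable", "value"]
        missing = [c for c in need if c not in raw.columns]
        if missing:
            raise ValueError(f"long panel file missing columns: {missing}")
        unknown = sorted(set(raw["variable"]) - set(_VALUE_VARS))
        if unknown:
            raise ValueError(f"unknown variable names: {unknown}")
        dup = raw.duplicated(subset=["participant_id", "wave", "variable"])
        if dup.any():
            lines = (raw.index[dup] + 2).tolist()
            raise ValueError(
                f"duplicate (participant, wave, variable) rows at lines {lines}")
        meta_cols = [c for c in _META if c in raw.columns]
        meta = raw[meta_cols].drop_duplicates(["participant_id", "wave"])
        wide = raw.pivot(index=["participant_id", "wave"], columns="variable",
                         values="value").reset_index()
        wide.columns.name = None
        wide = wide.merge(meta, on=["participant_id", "wave"], how="left")
        return PanelDataset(_canonical_wide(wide))
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# config serialization


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def generator_config_to_dict(config: GeneratorConfig) -> dict:
    return _to_plain(asdict(config))


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    tn = dict(d.pop("true_network"))
    tn["lag_matrix_by_wavepair"] = tuple(
        np.asarray(m, dtype=float) for m in tn["lag_matrix_by_wavepair"])
    d["true_network"] = TrueNetwork(**tn)
    d["measurement"] = MeasurementModel(**d.pop("measurement"))
    d["attrition"] = AttritionModel(**d.pop("attrition"))
    d["age_mean_by_wave"] = tuple(d["age_mean_by_wave"])
    return GeneratorConfig(**d)


def save_config_yaml(config, path) -> None:
    payload = generator_config_to_dict(config) if is_dataclass(config) else config
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        return generator_config_from_dict(yaml.safe_load(fh))
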