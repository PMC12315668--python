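"""Data cleaning and node construction for the panel analyses.

The rules implemented here, in order of application for a wave-pair
analysis:

1. outlier removal — cells of the go/no-go summaries with a single-pass
   absolute z-score >= 4 are set missing, per variable per wave;
2. inclusion — complete cases on all wave-1 measures, and for the
   wave-2 -> wave-3 analysis additionally complete on the wave-pair nodes
   (which subsumes the requirement of available wave-3 symptom scales);
3. symptom harmonization — broad-band scores z-standardized separately
   within CBCL and ABCL subgroups before pooling;
4. working-memory aggregation — backward digit and corsi spans each
   z-standardized then averaged per participant;
5. orientation — RT and commission errors negated so higher = better on
   every cognitive node;
6. per-wave standardization of the five analysis nodes on the analysis
   sample.

Every transformation is recorded in a :class:`PreprocessReport` whose
steps can be replayed on the raw input to reproduce the node table
bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NODES, OBSERVED_VARIABLES, PanelDataset

__all__ = [
    "VariableSpec",
    "PreprocessReport",
    "default_variable_specs",
    "remove_outliers",
    "invert_orientation",
    "aggregate_working_memory",
    "harmonize_scales",
    "complete_case_filter",
    "standardize_nodes",
    "build_node_table",
    "replay_report",
]

OUTLIER_VARIABLES = ("go_rt", "commission_errors")


@dataclass(frozen=True)
class VariableSpec:
    """Role and handling of one measured variable."""

    name: str
    role: str  # symptom | cognitive | covariate
    orientation: str = "keep"  # keep | invert
    aggregation_group: str | None = None
    instrument: str = "task"  # cbcl | abcl | task
    wave_availability: tuple = (1, 2, 3)

    def __post_init__(self):
        if self.role not in ("symptom", "cognitive", "covariate"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.orientation not in ("keep", "invert"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.orientation == "invert" and self.role != "cognitive":
            raise ValueError("inversion only applies to cognitive variables")


def default_variable_specs() -> list[VariableSpec]:
    return [
        VariableSpec("internalizing", "symptom", instrument="cbcl"),
        VariableSpec("externalizing", "symptom", instrument="cbcl"),
        VariableSpec("digit_backward", "cognitive", aggregation_group="working_memory"),
        VariableSpec("corsi_backward", "cognitive", aggregation_group="working_memory"),
        VariableSpec("go_rt", "cognitive", orientation="invert"),
        VariableSpec("commission_errors", "cognitive", orientation="invert"),
        VariableSpec("age", "covariate"),
        VariableSpec("gender", "covariate"),
    ]


@dataclass
class PreprocessReport:
    """Replayable audit trail of a preprocessing run."""

    n_input: int = 0
    n_after_complete_case: int = 0
    n_outlier_cells_removed: dict = field(default_factory=dict)
    standardization_params: dict = field(default_factory=dict)
    steps: list = field(default_factory=list)

    def record(self, op: str, **params) -> None:
        self.steps.append({"op": op, **params})

    def to_json(self, path=None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_after_complete_case": self.n_after_complete_case,
            "n_outlier_cells_removed": self.n_outlier_cells_removed,
            "standardization_params": self.standardization_params,
            "steps": self.steps,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# elementary operations


def remove_outliers(values, threshold: float = 4.0, *, moments=None):
    """Set cells with single-pass |z| >= threshold missing.

    Mean and SD are computed once on the non-missing values (no iterative
    re-standardization).  A zero-SD vector is returned untouched with a
    warning.  Returns ``(cleaned, n_removed, (mean, sd))``; ``moments`` can
    be supplied to replay a recorded transformation.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = pd.Series(np.asarray(values, dtype=float))
    obs = x.dropna()
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values")
    if moments is None:
        mean, sd = float(obs.mean()), float(obs.std(ddof=1))
    else:
        mean, sd = moments
    if sd == 0:
        warnings.warn("zero SD: outlier rule removes nothing", stacklevel=2)
        return x.to_numpy(), 0, (mean, sd)
    z = (x - mean).abs() / sd
    mask = z >= threshold
    out = x.mask(mask)
    return out.to_numpy(), int(mask.sum()), (mean, sd)


def invert_orientation(values, spec: VariableSpec):
    """Negate a cognitive score so that higher = better; NaN preserved."""
    if spec.orientation != "invert":
        raise ValueError(f"variable {spec.name!r} is not marked for inversion")
    return -np.asarray(values, dtype=float)


def _zscore(x: pd.Series, moments=None):
    obs = x.dropna()
    if moments is None:
        mean, sd = float(obs.mean()), float(obs.std(ddof=1))
    else:
        mean, sd = moments
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or undefined SD; cannot standardize")
    return (x - mean) / sd, (mean, sd)


def aggregate_working_memory(digit_backward, corsi_backward, *, moments=None):
    """z-standardize each backward span, then average per participant.

    A participant missing either indicator gets a missing aggregate (no
    single-indicator fallback).  Returns ``(aggregate, params)`` where
    params holds the standardization moments used.
    """
    d = pd.Series(np.asarray(digit_backward, dtype=float))
    c = pd.Series(np.asarray(corsi_backward, dtype=float))
    if len(d) != len(c):
        raise ValueError("indicator sequences must be aligned by participant")
    if d.notna().sum() < 3 or c.notna().sum() < 3:
        raise ValueError("need at least 3 non-missing values per indicator")
    mom = moments or {}
    dz, md = _zscore(d, mom.get("digit_backward"))
    cz, mc = _zscore(c, mom.get("corsi_backward"))
    agg = (dz + cz) / 2.0  # NaN-propagating mean
    return agg.to_numpy(), {"digit_backward": md, "corsi_backward": mc}


def harmonize_scales(scores, instrument_labels, *, moments=None):
    """z-standardize a symptom scale separately within each instrument.

    Children assessed with the CBCL and adults with the ABCL are pooled on
    a common z-scale by standardizing each subgroup to mean 0, SD 1.
    Returns ``(harmonized, {instrument: (mean, sd)})``.
    """
    x = pd.Series(np.asarray(scores, dtype=float))
    labels = pd.Series(instrument_labels).reset_index(drop=True)
    if len(x) != len(labels):
        raise ValueError("scores and instrument labels must align")
    out = pd.Series(np.nan, index=x.index)
    params = {}
    for inst in labels.dropna().unique():
        mask = (labels == inst).to_numpy()
        sub = x[mask]
        if sub.notna().sum() < 3:
            raise ValueError(f"instrument subgroup {inst!r} has < 3 observed scores")
        known = None if moments is None else moments.get(inst)
        try:
            z, mom = _zscore(sub, known)
        except ValueError as err:
            raise ValueError(f"instrument subgroup {inst!r}: {err}") from err
        out[mask] = z
        params[inst] = mom
    return out.to_numpy(), params


def complete_case_filter(data: PanelDataset, required_wave1_variables,
                         extra_required: dict | None = None) -> PanelDataset:
    """Keep participants observed on every required variable.

    ``required_wave1_variables`` applies at wave 1; ``extra_required`` maps
    further waves to variable lists (e.g. wave-3 symptom scales for the
    second analysis).  Participants failing any rule are removed entirely.
    """
    required = {1: list(required_wave1_variables)}
    for w, cols in (extra_required or {}).items():
        required.setdefault(int(w), []).extend(cols)

    keep = None
    for w, cols in required.items():
        missing_cols = [c for c in cols if c not in data.table.columns]
        if missing_cols:
            raise KeyError(f"unknown required variables: {missing_cols}")
        sub = data.wave(w)
        ok = set(sub.index[sub[cols].notna().all(axis=1)])
        keep = ok if keep is None else keep & ok
    table = data.table[data.table["participant_id"].isin(keep)]
    if table.empty:
        raise ValueError("complete-case filter removed every participant")
    return PanelDataset(table.copy())


def standardize_nodes(frame: pd.DataFrame, node_columns, per_wave: bool = True,
                      *, moments=None):
    """z-score node columns (within wave when ``per_wave``) on the sample.

    Returns ``(standardized frame, {(column, wave): (mean, sd)})``.
    """
    out = frame.copy()
    params = {}
    groups = out.groupby("wave").groups if per_wave else {"all": out.index}
    for col in node_columns:
        for wv, idx in groups.items():
            sub = out.loc[idx, col]
            if sub.notna().sum() < 3:
                raise ValueError(f"node {col!r} wave {wv}: fewer than 3 observed values")
            known = None if moments is None else moments[f"{col}@{wv}"]
            try:
                z, mom = _zscore(sub, known)
            except ValueError as err:
                raise ValueError(f"node {col!r} wave {wv}: {err}") from err
            out.loc[idx, col] = z
            params[f"{col}@{wv}"] = mom
    return out, params


# ---------------------------------------------------------------------------
# the analysis-table builder


def build_node_table(data: PanelDataset, wave_pair=(1, 2), *,
                     outlier_threshold: float = 4.0, report=None):
    """Produce the standardized five-node analysis table for one wave pair.

    Returns ``(node_table, PreprocessReport)``; the table has one row per
    retained participant x wave (both waves of the pair) with columns
    participant_id, wave, age, gender, and the five network nodes.
    Passing a previously produced ``report`` replays its recorded
    parameters instead of re-estimating them.
    """
    t0, t1 = wave_pair
    if t1 != t0 + 1 or t0 not in (1, 2):
        raise ValueError("wave_pair must be (1, 2) or (2, 3)")
    replay = report is not None
    rep = report if replay else PreprocessReport()
    rep_steps = iter(rep.steps) if replay else None

    def next_step(op):
        step = next(rep_steps)
        assert step["op"] == op, f"replay mismatch: {step['op']} != {op}"
        return step

    if not replay:
        rep.n_input = data.n_participants

    table = data.table.copy()

    # 1. outlier removal, per task variable per wave
    for var in OUTLIER_VARIABLES:
        for w in (1, 2, 3):
            idx = table.index[table["wave"] == w]
            if replay:
                step = next_step("remove_outliers")
                cleaned, n_rm, mom = remove_outliers(
                    table.loc[idx, var], step["threshold"], moments=step["moments"])
            else:
                cleaned, n_rm, mom = remove_outliers(
                    table.loc[idx, var], outlier_threshold)
                rep.record("remove_outliers", variable=var, wave=w,
                           threshold=outlier_threshold, moments=list(mom))
                rep.n_outlier_cells_removed[f"{var}@{w}"] = n_rm
            table.loc[idx, var] = cleaned
    cleaned_panel = PanelDataset(table)

    # 2. inclusion rules
    extra = {t0: list(OBSERVED_VARIABLES), t1: list(OBSERVED_VARIABLES)}
    filtered = complete_case_filter(
        cleaned_panel, list(OBSERVED_VARIABLES), extra_required=extra)
    if not replay:
        rep.record("complete_case", wave_pair=list(wave_pair))
        rep.n_after_complete_case = filtered.n_participants
    else:
        next_step("complete_case")

    sub = filtered.table[filtered.table["wave"].isin(wave_pair)].copy()

    # 3. symptom harmonization per wave (CBCL/ABCL standardized separately)
    for var in ("internalizing", "externalizing"):
        for w in wave_pair:
            idx = sub.index[sub["wave"] == w]
            if replay:
                step = next_step("harmonize")
                z, mom = harmonize_scales(
                    sub.loc[idx, var], sub.loc[idx, "instrument"],
                    moments={k: tuple(v) for k, v in step["moments"].items()})
            else:
                z, mom = harmonize_scales(sub.loc[idx, var], sub.loc[idx, "instrument"])
                rep.record("harmonize", variable=var, wave=w,
                           moments={k: list(v) for k, v in mom.items()})
                for inst, m in mom.items():
                    rep.standardization_params[f"{var}@{w}:{inst}"] = list(m)
            sub.loc[idx, var] = z

    # 4. working-memory aggregate per wave
    sub["working_memory"] = np.nan
    for w in wave_pair:
        idx = sub.index[sub["wave"] == w]
        if replay:
            step = next_step("aggregate_wm")
            agg, mom = aggregate_working_memory(
                sub.loc[idx, "digit_backward"], sub.loc[idx, "corsi_backward"],
                moments={k: tuple(v) for k, v in step["moments"].items()})
        else:
            agg, mom = aggregate_working_memory(
                sub.loc[idx, "digit_backward"], sub.loc[idx, "corsi_backward"])
            rep.record("aggregate_wm", wave=w,
                       moments={k: list(v) for k, v in mom.items()})
        sub.loc[idx, "working_memory"] = agg

    # 5. orientation: higher = better on both inhibitory-control indices
    specs = {s.name: s for s in default_variable_specs()}
    sub["inhibition_speed"] = invert_orientation(sub["go_rt"], specs["go_rt"])
    sub["inhibition_accuracy"] = invert_orientation(
        sub["commission_errors"], specs["commission_errors"])
    if not replay:
        rep.record("invert", variables=["go_rt", "commission_errors"])
    else:
        next_step("invert")

    # 6. per-wave standardization of the analysis nodes
    node_cols = list(NODES)
    keep_cols = ["participant_id", "wave", "age", "gender"] + node_cols
    out = sub[keep_cols].reset_index(drop=True)
    if replay:
        step = next_step("standardize_nodes")
        out, params = standardize_nodes(
            out, node_cols, per_wave=True,
            moments={k: tuple(v) for k, v in step["moments"].items()})
    else:
        out, params = standardize_nodes(out, node_cols, per_wave=True)
        rep.record("standardize_nodes",
                   moments={k: list(v) for k, v in params.items()})
        for k, v in params.items():
            rep.standardization_params[k] = list(v)

    out = out.sort_values(["participant_id", "wave"], kind="mergesort").reset_index(drop=True)
    return out, rep


def replay_report(data: PanelDataset, wave_pair, report: PreprocessReport):
    """Reapply a recorded preprocessing run; bit-identical to the original."""
    table, _ = build_node_table(data, wave_pair, report=report)
    return table
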