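"""Cross-lagged panel network estimation for one wave pair.

Each node measured at wave t+1 is regressed on all five nodes at wave t
plus predictor-only covariates (age at wave t by default, optionally
gender) using the L1 solver with 10-fold cross-validated penalty
selection.  Covariates are never targets.  The node-wise coefficient
vectors are assembled into a source x target matrix whose diagonal
carries the autoregressive effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NODES
from .lasso import build_lambda_path, cv_select_lambda, lasso_fit

__all__ = ["NodeRegression", "CrossLaggedNetwork", "fit_clpn", "node_table_from_latents"]


@dataclass
class NodeRegression:
    """One penalized regression: a wave-(t+1) target on wave-t predictors."""

    target: str
    predictors: list
    coefficients: np.ndarray  # aligned with predictors, standardized scale
    intercept: float
    selected_lambda: float
    cv_lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray

    def coef(self, predictor: str) -> float:
        return float(self.coefficients[self.predictors.index(predictor)])


@dataclass
class CrossLaggedNetwork:
    """Directed lagged network: matrix[i, j] = effect of node i at wave t
    on node j at wave t+1 (autoregression on the diagonal); covariate
    effects are kept separate because covariates have no incoming edges."""

    wave_pair: tuple
    nodes: tuple
    matrix: np.ndarray
    covariate_effects: dict = field(default_factory=dict)
    lambdas_by_target: dict = field(default_factory=dict)
    n_used: int = 0
    regressions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.nodes)
        if self.matrix.shape != (p, p):
            raise ValueError(f"matrix must be {p}x{p}")
        for cov, row in self.covariate_effects.items():
            if cov in self.nodes:
                raise ValueError(f"covariate {cov!r} collides with a node")
            self.covariate_effects[cov] = np.asarray(row, dtype=float)

    @property
    def covariates(self) -> tuple:
        return tuple(self.covariate_effects)

    def edge(self, source: str, target: str) -> float:
        if source in self.covariate_effects:
            return float(self.covariate_effects[source][self.nodes.index(target)])
        return float(self.matrix[self.nodes.index(source), self.nodes.index(target)])

    def to_matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.nodes),
                            columns=list(self.nodes))

    def to_edge_list(self) -> pd.DataFrame:
        """Tidy directed edges: lagged, autoregressive, and covariate rows."""
        rows = []
        pair = f"{self.wave_pair[0]}-{self.wave_pair[1]}"
        for i, src in enumerate(self.nodes):
            for j, tgt in enumerate(self.nodes):
                rows.append({
                    "source": src, "target": tgt,
                    "weight": self.matrix[i, j], "wave_pair": pair,
                    "type": "autoregressive" if i == j else "lagged",
                })
        for cov, row in self.covariate_effects.items():
            for j, tgt in enumerate(self.nodes):
                rows.append({"source": cov, "target": tgt, "weight": row[j],
                             "wave_pair": pair, "type": "covariate"})
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "wave_pair": list(self.wave_pair),
            "nodes": list(self.nodes),
            "matrix": self.matrix.tolist(),
            "covariate_effects": {k: v.tolist() for k, v in self.covariate_effects.items()},
            "lambdas_by_target": self.lambdas_by_target,
            "n_used": self.n_used,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_matrix(cls, matrix, wave_pair=(1, 2), nodes=NODES,
                    covariate_effects=None) -> "CrossLaggedNetwork":
        return cls(wave_pair=tuple(wave_pair), nodes=tuple(nodes),
                   matrix=np.asarray(matrix, dtype=float),
                   covariate_effects=dict(covariate_effects or {}))

    @classmethod
    def from_json(cls, path) -> "CrossLaggedNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(wave_pair=tuple(payload["wave_pair"]),
                   nodes=tuple(payload["nodes"]),
                   matrix=np.asarray(payload["matrix"], dtype=float),
                   covariate_effects={k: np.asarray(v, dtype=float)
                                      for k, v in payload["covariate_effects"].items()},
                   lambdas_by_target=payload.get("lambdas_by_target", {}),
                   n_used=payload.get("n_used", 0))


def _standardize_column(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant covariate")
    return (x - x.mean()) / sd


def _fit_node_regressions(X, Y, X_cols, k, seed, rule, n_lambdas, ratio_min,
                          folds):
    """Array-level core: one penalized regression per target column of Y.

    X is (n, n_nodes + n_covariates); Y is (n, n_nodes) aligned with NODES.
    Returns (matrix, covariate coefficient block, lambdas, regressions).
    """
    n, q = X.shape
    p = len(NODES)
    if folds is None:
        rng = np.random.default_rng(seed)
        folds = rng.permutation(n) % k
    matrix = np.zeros((p, p))
    cov_block = np.zeros((q - p, p))
    lambdas_by_target = {}
    regressions = {}
    for j, target in enumerate(NODES):
        y = Y[:, j]
        if y.std(ddof=1) == 0:
            raise ValueError(f"target node {target!r} is constant")
        path = build_lambda_path(X, y, n_lambdas=n_lambdas, ratio_min=ratio_min)
        lam, cv_mean, cv_se = cv_select_lambda(X, y, path, k=k, seed=seed,
                                               rule=rule, folds=folds)
        coef, intercept = lasso_fit(X, y, lam)
        matrix[:, j] = coef[:p]
        cov_block[:, j] = coef[p:]
        lambdas_by_target[target] = lam
        regressions[target] = NodeRegression(
            target=target, predictors=X_cols, coefficients=coef,
            intercept=intercept, selected_lambda=lam,
            cv_lambdas=path.lambdas, cv_mean=cv_mean, cv_se=cv_se)
    return matrix, cov_block, lambdas_by_target, regressions


def prepare_wave_pair_arrays(node_table: pd.DataFrame, wave_pair=(1, 2),
                             covariates=("age",)):
    """Complete-case predictor/response arrays for one wave pair.

    Returns ``(X, Y, X_cols)`` with X = wave-t nodes plus standardized
    covariates and Y = wave-(t+1) nodes, row-aligned by participant.
    """
    t0, t1 = wave_pair
    left = node_table[node_table["wave"] == t0].set_index("participant_id")
    right = node_table[node_table["wave"] == t1].set_index("participant_id")
    common = left.index.intersection(right.index)
    left, right = left.loc[common], right.loc[common]
    need = list(NODES) + list(covariates)
    ok = left[need].notna().all(axis=1) & right[list(NODES)].notna().all(axis=1)
    left, right = left[ok], right[ok]
    X = np.column_stack(
        [left[c].to_numpy(dtype=float) for c in NODES]
        + [_standardize_column(left[c].to_numpy(dtype=float)) for c in covariates]
    )
    Y = np.column_stack([right[c].to_numpy(dtype=float) for c in NODES])
    return X, Y, list(NODES) + list(covariates)


def fit_clpn(node_table: pd.DataFrame, wave_pair=(1, 2), covariates=("age",),
             k: int = 10, seed: int = 0, rule: str = "min",
             n_lambdas: int = 100, ratio_min: float = 1e-3,
             folds=None) -> CrossLaggedNetwork:
    """Estimate the cross-lagged network for one wave pair.

    ``node_table`` is the preprocessed long table (one row per participant
    x wave with the five standardized node columns plus age/gender).
    Complete cases across both waves of the pair are used.  One fold
    assignment (seeded, shared across the five target regressions) governs
    CV; ``folds`` may override it with explicit labels.
    """
    covariates = tuple(covariates)
    for cov in covariates:
        if cov in NODES:
            raise ValueError(f"covariate {cov!r} is a network node")

    X, Y, X_cols = prepare_wave_pair_arrays(node_table, wave_pair, covariates)
    n = len(X)
    if n < max(k, 10):
        raise ValueError(f"only {n} complete cases for wave pair {wave_pair}")

    try:
        matrix, cov_block, lambdas_by_target, regressions = _fit_node_regressions(
            X, Y, X_cols, k, seed, rule, n_lambdas, ratio_min, folds)
    except ValueError as err:
        if "constant" in str(err):
            raise ValueError(f"{err} at wave {wave_pair[1]}") from None
        raise
    cov_effects = {c: cov_block[ci] for ci, c in enumerate(covariates)}

    return CrossLaggedNetwork(
        wave_pair=tuple(wave_pair), nodes=NODES, matrix=matrix,
        covariate_effects=cov_effects, lambdas_by_target=lambdas_by_target,
        n_used=n, regressions=regressions)


def node_table_from_latents(panel, wave_pair=(1, 2)) -> pd.DataFrame:
    """Analysis table built directly from the generating latents.

    Bypasses the measurement layer (no indicator noise, no aggregation),
    standardizing each latent within wave.  Used to validate the estimator
    against ground truth free of measurement attenuation.
    """
    rows = panel.table[panel.table["wave"].isin(wave_pair)]
    out = rows[["participant_id", "wave", "age", "gender"]].copy()
    for node in NODES:
        out[node] = rows[f"latent_{node}"].to_numpy()
    out = out.dropna(subset=list(NODES)).reset_index(drop=True)
    for node in NODES:
        for w in wave_pair:
            idx = out.index[out["wave"] == w]
            x = out.loc[idx, node]
            out.loc[idx, node] = (x - x.mean()) / x.std(ddof=1)
    return out
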