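"""Edge-weight accuracy by nonparametric bootstrap.

Participants (both waves' records together) are resampled with
replacement at the original sample size; the full estimator — including
cross-validated penalty selection — is refit on every replicate.  Each
directed edge gets the replicate mean, SD, 2.5/97.5 percentile interval,
and the proportion of replicates in which it was selected (nonzero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NODES
from .network import (
    CrossLaggedNetwork,
    _fit_node_regressions,
    prepare_wave_pair_arrays,
)

__all__ = ["BootstrapResult", "bootstrap_network", "summarize_edges"]


@dataclass
class BootstrapResult:
    wave_pair: tuple
    nodes: tuple
    covariates: tuple
    b: int
    n_failures: int
    seed: int
    # arrays of shape (p, p) for lagged edges; {cov: (p,)} for covariates
    mean: np.ndarray = field(repr=False, default=None)
    sd: np.ndarray = field(repr=False, default=None)
    lower: np.ndarray = field(repr=False, default=None)
    upper: np.ndarray = field(repr=False, default=None)
    inclusion: np.ndarray = field(repr=False, default=None)
    cov_summaries: dict = field(repr=False, default_factory=dict)

    def summary_table(self) -> pd.DataFrame:
        """Tidy per-edge summaries (lagged + covariate edges)."""
        rows = []
        for i, src in enumerate(self.nodes):
            for j, tgt in enumerate(self.nodes):
                rows.append({
                    "source": src, "target": tgt,
                    "type": "autoregressive" if i == j else "lagged",
                    "boot_mean": self.mean[i, j], "boot_sd": self.sd[i, j],
                    "ci_lower": self.lower[i, j], "ci_upper": self.upper[i, j],
                    "inclusion_proportion": self.inclusion[i, j],
                })
        for cov, s in self.cov_summaries.items():
            for j, tgt in enumerate(self.nodes):
                rows.append({
                    "source": cov, "target": tgt, "type": "covariate",
                    "boot_mean": s["mean"][j], "boot_sd": s["sd"][j],
                    "ci_lower": s["lower"][j], "ci_upper": s["upper"][j],
                    "inclusion_proportion": s["inclusion"][j],
                })
        return pd.DataFrame(rows)


def bootstrap_network(node_table: pd.DataFrame, wave_pair=(1, 2), b: int = 1000,
                      seed: int = 0, fit_options: dict | None = None,
                      max_failure_fraction: float = 0.1) -> BootstrapResult:
    """Resample participants with replacement and refit the network b times.

    Deterministic under ``seed``.  Replicates that fail to fit are recorded
    and skipped; more than ``max_failure_fraction`` failures is an error.
    """
    if b < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    fit_options = dict(fit_options or {})
    covariates = tuple(fit_options.pop("covariates", ("age",)))
    k = fit_options.pop("k", 10)
    rule = fit_options.pop("rule", "min")
    n_lambdas = fit_options.pop("n_lambdas", 100)
    ratio_min = fit_options.pop("ratio_min", 1e-3)
    fit_options.pop("seed", None)
    if fit_options:
        raise TypeError(f"unknown fit options: {sorted(fit_options)}")

    # resampling unit: whole participants, both waves' records together
    X, Y, X_cols = prepare_wave_pair_arrays(node_table, wave_pair, covariates)
    n = len(X)
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2**31 - 1, size=b)

    mats, covs = [], []
    n_fail = 0
    for r in range(b):
        take = rng.integers(0, n, size=n)
        try:
            matrix, cov_block, _, _ = _fit_node_regressions(
                X[take], Y[take], X_cols, k, int(fit_seeds[r]), rule,
                n_lambdas, ratio_min, None)
        except (ValueError, RuntimeError):
            n_fail += 1
            continue
        mats.append(matrix)
        covs.append(cov_block)

    if n_fail > max_failure_fraction * b:
        raise RuntimeError(f"{n_fail}/{b} bootstrap replicates failed to fit")

    stack = np.stack(mats)  # (b_ok, p, p)
    result = BootstrapResult(
        wave_pair=tuple(wave_pair), nodes=tuple(NODES),
        covariates=covariates, b=b, n_failures=n_fail, seed=seed,
        mean=stack.mean(axis=0), sd=stack.std(axis=0, ddof=1),
        lower=np.percentile(stack, 2.5, axis=0),
        upper=np.percentile(stack, 97.5, axis=0),
        inclusion=(stack != 0).mean(axis=0),
    )
    for ci, cov in enumerate(covariates):
        cstack = np.stack([c[ci] for c in covs])
        result.cov_summaries[cov] = {
            "mean": cstack.mean(axis=0), "sd": cstack.std(axis=0, ddof=1),
            "lower": np.percentile(cstack, 2.5, axis=0),
            "upper": np.percentile(cstack, 97.5, axis=0),
            "inclusion": (cstack != 0).mean(axis=0),
        }
    return result


def summarize_edges(result: BootstrapResult,
                    point_network: CrossLaggedNetwork) -> pd.DataFrame:
    """Join point estimates with bootstrap summaries per directed edge.

    Adds the point weight and a flag for edges whose percentile interval
    excludes zero.  Row count is n_nodes^2 + n_covariates * n_nodes.
    """
    if tuple(result.nodes) != tuple(point_network.nodes):
        raise ValueError("node sets of bootstrap result and network differ")
    table = result.summary_table()
    table["point_weight"] = [
        point_network.edge(s, t) for s, t in zip(table["source"], table["target"])
    ]
    table["excludes_zero"] = (table["ci_lower"] > 0) | (table["ci_upper"] < 0)
    cols = ["source", "target", "type", "point_weight", "boot_mean", "boot_sd",
            "ci_lower", "ci_upper", "inclusion_proportion", "excludes_zero"]
    return table[cols]
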