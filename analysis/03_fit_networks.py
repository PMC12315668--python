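#!/usr/bin/env python
"""Estimate the cross-lagged networks for both wave transitions.

Node-wise LASSO with 10-fold cross-validated penalty selection, age as a
predictor-only covariate, for waves 1->2 and 2->3, plus the gender
sensitivity refit (age + gender).  Writes edge lists, matrices, and a
between-wave-pair comparison.
"""

import json
from pathlib import Path

import pandas as pd

from clpnet.evaluation import compare_networks, network_density
from clpnet.network import fit_clpn

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 21


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    nets = {}
    for pair in ((1, 2), (2, 3)):
        tag = f"w{pair[0]}{pair[1]}"
        path = SCRATCH / f"nodes_{tag}.csv"
        if not path.exists():
            raise SystemExit("run analysis/02_preprocess.py first")
        table = pd.read_csv(path)
        net = fit_clpn(table, pair, covariates=("age",), seed=SEED)
        nets[pair] = net
        net.to_json(RESULTS / f"network_{tag}.json")
        net.to_edge_list().to_csv(RESULTS / f"edges_{tag}.csv", index=False)
        net.to_matrix_frame().round(4).to_csv(RESULTS / f"matrix_{tag}.csv")
        print(f"waves {pair[0]}->{pair[1]}: n={net.n_used}, "
              f"density {network_density(net):.2f} "
              f"({int(network_density(net) * 25)}/25 nonzero lagged edges)")

        sens = fit_clpn(table, pair, covariates=("age", "gender"), seed=SEED)
        sens.to_edge_list().to_csv(
            RESULTS / f"edges_{tag}_gender_covariate.csv", index=False)

    comparison = compare_networks(nets[(1, 2)], nets[(2, 3)])
    with open(RESULTS / "network_comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, default=str)
    print(f"support overlap (Jaccard): {comparison['support_jaccard']:.2f}; "
          f"weight correlation: {comparison['weight_correlation']:.2f}")


if __name__ == "__main__":
    main()
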