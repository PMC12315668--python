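#!/usr/bin/env python
"""Parameter-recovery experiment against generator truth.

Simulates cohorts with uniform |beta| = 0.3 cross-lagged effects, runs
the full observed-data pipeline, and scores the estimated support
against truth over a grid of sample sizes.  Reports sensitivity,
specificity, sign accuracy, and weight correlation with Monte-Carlo SEs.
"""

from pathlib import Path

import pandas as pd

from clpnet.cohort import GeneratorConfig, uniform_effect_network
from clpnet.evaluation import run_recovery_experiment

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
REPS = 25
N_GRID = (500, 1000, 2000)


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(true_network=uniform_effect_network(0.3),
                          target_attrition=0.0)
    reports = run_recovery_experiment(cfg, reps=REPS, n_grid=N_GRID, seed=41)
    rows = [{
        "n": r.n, "reps": r.reps,
        "sensitivity": r.sensitivity, "sensitivity_se": r.sensitivity_se,
        "specificity": r.specificity, "specificity_se": r.specificity_se,
        "sign_accuracy": r.sign_accuracy,
        "weight_correlation": r.weight_correlation,
    } for r in reports]
    table = pd.DataFrame(rows)
    table.round(4).to_csv(RESULTS / "recovery_experiment.csv", index=False)
    for row in rows:
        print(f"n={row['n']:>5}: sensitivity {row['sensitivity']:.3f} "
              f"(SE {row['sensitivity_se']:.3f}), "
              f"specificity {row['specificity']:.3f}, "
              f"sign accuracy {row['sign_accuracy']:.3f}")


if __name__ == "__main__":
    main()
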