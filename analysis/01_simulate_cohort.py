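#!/usr/bin/env python
"""Simulate the synthetic three-wave at-risk cohort.

Generates n = 1,992 participants (the wave-1 size of the cohort the
design emulates) with the default configuration: 60.89% high-risk
oversampling, wave mean ages 10.20 / 13.48 / 18.20, sparse cross-lagged
truth, and informative attrition calibrated to 35.14% whose probability
decreases with wave-1 internalizing.  The full panel (bulky, fully
regenerable from the seed) goes to scratch/; a small calibration summary
goes to results/.
"""

import json
from pathlib import Path

import numpy as np

from clpnet.cohort import apply_attrition, attrition_rate, default_config, simulate_cohort
from clpnet.io import save_config_yaml, write_panel_csv

SEED = 11
N = 1992

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    cfg = default_config(N, seed=SEED)
    panel = simulate_cohort(cfg)
    panel = apply_attrition(panel, cfg.attrition, seed=SEED + 1,
                            target_attrition=cfg.target_attrition)

    write_panel_csv(panel, SCRATCH / "cohort_wide.csv", "wide")
    write_panel_csv(panel, SCRATCH / "cohort_long.csv", "long")
    save_config_yaml(cfg, SCRATCH / "generator_config.yaml")

    w1 = panel.wave(1)
    stats = {
        "n_participants": panel.n_participants,
        "seed": SEED,
        "high_risk_fraction": float(
            (panel.table.groupby("participant_id").first()["group"]
             == "high_risk").mean()),
        "attrition_rate": attrition_rate(panel),
        "wave1_span_correlation": float(
            np.corrcoef(w1["digit_backward"], w1["corsi_backward"])[0, 1]),
        "n_observed_by_wave": {
            w: int(panel.wave(w)["internalizing"].notna().sum()) for w in (1, 2, 3)
        },
    }
    with open(RESULTS / "cohort_calibration.json", "w") as fh:
        json.dump(stats, fh, indent=2)

    print(f"simulated {stats['n_participants']} participants (seed {SEED})")
    print(f"  high-risk fraction: {stats['high_risk_fraction']:.4f} (target 0.6089)")
    print(f"  attrition rate:     {stats['attrition_rate']:.4f} (target 0.3514)")
    print(f"  digit/corsi r at wave 1: {stats['wave1_span_correlation']:.3f} (target 0.46)")
    print(f"  observed per wave: {stats['n_observed_by_wave']}")
    print(f"panel written to {SCRATCH}")


if __name__ == "__main__":
    main()
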