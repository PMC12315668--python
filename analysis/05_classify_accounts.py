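#!/usr/bin/env python
"""Classify EF-psychopathology links as risk factors, consequences, or both.

For each (executive function, symptom domain) pair and each wave
transition, the presence of the two directed edges decides the label:
EF -> symptom only = risk factor, symptom -> EF only = consequence,
both directions = both.  Inclusion proportions from the bootstrap are
merged in for reference.
"""

from pathlib import Path

import pandas as pd

from clpnet.evaluation import classify_accounts
from clpnet.network import CrossLaggedNetwork

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    frames = []
    for pair in ((1, 2), (2, 3)):
        tag = f"w{pair[0]}{pair[1]}"
        net_path = RESULTS / f"network_{tag}.json"
        if not net_path.exists():
            raise SystemExit("run analysis/03_fit_networks.py first")
        net = CrossLaggedNetwork.from_json(net_path)
        cls = classify_accounts(net)
        frame = cls.to_frame()
        acc_path = RESULTS / f"edge_accuracy_{tag}.csv"
        if acc_path.exists():
            acc = pd.read_csv(acc_path)[["source", "target", "inclusion_proportion"]]
            frame = frame.merge(
                acc.rename(columns={"source": "ef_node", "target": "symptom_node",
                                    "inclusion_proportion": "inclusion_ef_to_symptom"}),
                on=["ef_node", "symptom_node"], how="left")
        frames.append(frame)
        print(f"waves {pair[0]}->{pair[1]}:")
        for _, row in frame.iterrows():
            print(f"  {row['ef_node']:>20} x {row['symptom_node']:<14} "
                  f"-> {row['account']}")
    pd.concat(frames, ignore_index=True).to_csv(
        RESULTS / "account_classification.csv", index=False)


if __name__ == "__main__":
    main()
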