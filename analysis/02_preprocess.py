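#!/usr/bin/env python
"""Build the analysis-ready node tables for both wave pairs.

Applies the cleaning rules — |z| >= 4 outlier removal on the go/no-go
summaries, wave-1 complete-case inclusion (plus wave-pair completeness),
CBCL/ABCL harmonization, working-memory aggregation, inversion of the
inhibitory-control indices, and per-wave standardization — and records a
replayable preprocessing report per analysis.
"""

from pathlib import Path

from clpnet.io import read_panel_table
from clpnet.preprocess import build_node_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def load_panel():
    path = SCRATCH / "cohort_wide.csv"
    if not path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    return read_panel_table(path, "wide")


def main():
    panel = load_panel()
    RESULTS.mkdir(parents=True, exist_ok=True)
    for pair in ((1, 2), (2, 3)):
        tag = f"w{pair[0]}{pair[1]}"
        table, report = build_node_table(panel, pair)
        table.to_csv(SCRATCH / f"nodes_{tag}.csv", index=False)
        report.to_json(RESULTS / f"preprocess_report_{tag}.json")
        removed = sum(report.n_outlier_cells_removed.values())
        print(f"wave pair {pair}: {report.n_input} -> "
              f"{report.n_after_complete_case} complete cases; "
              f"{removed} outlier cells removed; "
              f"{len(table)} node-table rows")


if __name__ == "__main__":
    main()
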