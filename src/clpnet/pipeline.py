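"""End-to-end reproducible pipeline.

Runs simulate -> attrition -> preprocess -> fit (both wave pairs) ->
bootstrap -> evaluate and writes every artifact plus a manifest with
content hashes, row counts, and the per-stage seeds.  A single global
seed is expanded into six stage seeds with ``numpy.random.SeedSequence``
(simulate, attrition, fit 1-2, fit 2-3, bootstrap 1-2, bootstrap 2-3),
so a config + seed reproduce every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cohort import GeneratorConfig, apply_attrition, attrition_rate, simulate_cohort
from .evaluation import classify_accounts, compare_networks, network_density
from .io import generator_config_to_dict, write_panel_csv
from .network import fit_clpn
from .preprocess import build_node_table
from .stability import bootstrap_network, summarize_edges

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "attrition", "fit_w12", "fit_w23",
           "bootstrap_w12", "bootstrap_w23")


@dataclass
class PipelineConfig:
    """Everything one run needs; fully serializable."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    folds: int = 10
    covariates: tuple = ("age",)
    penalty_rule: str = "min"
    bootstrap_b: int = 0  # 0 skips the bootstrap stage
    outlier_threshold: float = 4.0
    inclusion_threshold: float | None = None

    def stage_seeds(self) -> dict:
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {name: int(s & 0x7FFFFFFF) for name, s in zip(_STAGES, state)}


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are already on disk."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest = {
        "config": {
            "generator": generator_config_to_dict(config.generator),
            "seed": config.seed, "folds": config.folds,
            "covariates": list(config.covariates),
            "penalty_rule": config.penalty_rule,
            "bootstrap_b": config.bootstrap_b,
            "outlier_threshold": config.outlier_threshold,
        },
        "stage_seeds": seeds,
        "stages": {},
        "files": {},
        "row_counts": {},
    }
    files = {}
    stage = "simulate"
    try:
        gen = replace(config.generator, seed=seeds["simulate"])
        panel = simulate_cohort(gen)
        manifest["row_counts"]["cohort"] = len(panel.table)
        manifest["stages"]["simulate"] = "ok"

        stage = "attrition"
        if gen.target_attrition > 0:
            panel = apply_attrition(panel, gen.attrition, seeds["attrition"],
                                    target_attrition=gen.target_attrition)
            manifest["stages"]["attrition"] = "ok"
            manifest["attrition_rate"] = attrition_rate(panel)
        else:
            manifest["stages"]["attrition"] = "skipped (target_attrition=0)"
        files["cohort_wide.csv"] = lambda p: write_panel_csv(panel, p, "wide")
        files["cohort_long.csv"] = lambda p: write_panel_csv(panel, p, "long")
        for name, writer in files.items():
            writer(out / name)
        files.clear()

        networks = {}
        for pair, fit_key in (((1, 2), "fit_w12"), ((2, 3), "fit_w23")):
            stage = f"preprocess_w{pair[0]}{pair[1]}"
            table, report = build_node_table(
                panel, pair, outlier_threshold=config.outlier_threshold)
            tag = f"w{pair[0]}{pair[1]}"
            table.to_csv(out / f"nodes_{tag}.csv", index=False)
            report.to_json(out / f"preprocess_report_{tag}.json")
            manifest["row_counts"][f"nodes_{tag}"] = len(table)

            stage = fit_key
            net = fit_clpn(table, pair, covariates=config.covariates,
                           k=config.folds, seed=seeds[fit_key],
                           rule=config.penalty_rule)
            networks[pair] = (net, table)
            net.to_json(out / f"network_{tag}.json")
            net.to_edge_list().to_csv(out / f"edges_{tag}.csv", index=False)
            net.to_matrix_frame().to_csv(out / f"matrix_{tag}.csv")
            manifest["row_counts"][f"n_used_{tag}"] = net.n_used
            manifest.setdefault("densities", {})[tag] = network_density(net)
            manifest["stages"][fit_key] = "ok"

            boot_key = f"bootstrap_{tag}"
            stage = boot_key
            if config.bootstrap_b > 0:
                boot = bootstrap_network(
                    table, pair, b=config.bootstrap_b, seed=seeds[boot_key],
                    fit_options={"covariates": config.covariates,
                                 "k": config.folds, "rule": config.penalty_rule})
                summarize_edges(boot, net).to_csv(
                    out / f"edge_accuracy_{tag}.csv", index=False)
                manifest["stages"][boot_key] = "ok"
                boot_for_class = boot
            else:
                manifest["stages"][boot_key] = "skipped (b=0)"
                boot_for_class = None

            stage = f"classify_{tag}"
            cls = classify_accounts(
                net, bootstrap=boot_for_class,
                inclusion_threshold=config.inclusion_threshold)
            cls.to_frame().to_csv(out / f"accounts_{tag}.csv", index=False)

        stage = "compare"
        comparison = compare_networks(networks[(1, 2)][0], networks[(2, 3)][0])
        with open(out / "network_comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=2, sort_keys=True, default=str)
    except Exception as err:
        raise StageError(f"pipeline stage {stage!r} failed: {err}") from err

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["files"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
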