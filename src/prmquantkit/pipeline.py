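"""End-to-end orchestration: simulate → quantify → roll up → qPCR →
correlate, driven by a single config mapping, with a checksummed output
manifest.  Every source of randomness is routed through named seeds so a
config reproduces bit-identical artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import assay_design, correlation, protein_stats, qpcr_quant, simdata
from .prm_quant import quantify_runs

log = logging.getLogger("prmquantkit")

DEFAULT_CONFIG = {
    "panel": None,  # path to a panel CSV; None = bundled reference panel
    "output_dir": "pipeline_out",
    "thresholds": {"q_keep": 0.01, "q_remove": 0.05, "ppm": 5.0, "alpha": 0.05},
    "q_strict": False,
    "simulation": {
        "replicates_per_stage": 6,
        "noise_sd": 0.0,
        "rt_jitter_sd": 0.5,
        "ct_noise_sd": 0.15,
    },
    "seeds": {"truth": 11, "runs": 12, "qpcr": 13, "correlation": 14,
              "decoys": 15},
    "n_correlation_datasets": 1500,
}


def load_config(path: str | Path | None) -> dict:
    config = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> dict:
    """Run every stage and return the artifact manifest."""
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config["seeds"]
    alpha = config["thresholds"]["alpha"]
    sim_block = config["simulation"]

    if config.get("panel"):
        panel = assay_design.load_panel(config["panel"])
    else:
        panel = assay_design.load_reference_panel()
    log.info("panel: %d peptides, %d proteins", len(panel), len(panel.proteins))

    sim_config = simdata.SimulationConfig(
        replicates_per_stage=int(sim_block.get("replicates_per_stage", 6)),
        noise_sd=float(sim_block.get("noise_sd", 0.0)),
        rt_jitter_sd=float(sim_block.get("rt_jitter_sd", 0.5)),
        seed=int(seeds["runs"]),
    )
    truth = simdata.default_ground_truth(panel, seed=int(seeds["truth"]),
                                         stages=sim_config.stages)
    runs = simdata.simulate_experiment(sim_config, truth, panel)
    simdata.save_runs(runs, out_dir / "runs")
    simdata.save_truth(truth, out_dir / "truth.json")

    quant = quantify_runs(runs, panel, strict=bool(config.get("q_strict")),
                          seed=int(seeds["decoys"]))
    quant_path = out_dir / "quant.csv"
    quant.to_csv(quant_path, index=False)
    log.info("quantified %d peptide observations", len(quant))

    profiles = protein_stats.roll_up(quant, stage_order=list(sim_config.stages),
                                     alpha=alpha)
    profiles_path = out_dir / "protein_profiles.csv"
    profiles.to_csv(profiles_path, index=False)

    qtruth = simdata.default_qpcr_truth(
        panel.proteins, seed=int(seeds["qpcr"]), stages=sim_config.stages,
        ct_noise_sd=float(sim_block.get("ct_noise_sd", 0.15)),
    )
    cts = simdata.simulate_qpcr(qtruth, stages=sim_config.stages,
                                replicates=sim_config.replicates_per_stage,
                                seed=int(seeds["qpcr"]))
    cts_path = out_dir / "cts.csv"
    cts.to_csv(cts_path, index=False)
    expr = qpcr_quant.expression_profiles(cts, panel.proteins,
                                          stage_order=list(sim_config.stages),
                                          alpha=alpha)
    expr_path = out_dir / "expression_profiles.csv"
    expr.to_csv(expr_path, index=False)

    corr_records = []
    for protein in panel.proteins:
        prot = profiles[profiles["protein"] == protein]
        gene = expr[expr["gene"] == protein]
        if prot.empty or gene.empty:
            continue
        a = correlation.MeanSeProfile(
            label=f"protein:{protein}", stages=tuple(prot["stage"]),
            means=prot["estimate"].to_numpy(), ses=prot["se"].to_numpy(),
        )
        b = correlation.MeanSeProfile(
            label=f"mrna:{protein}", stages=tuple(gene["stage"]),
            means=gene["mean"].to_numpy(), ses=gene["se"].to_numpy(),
        )
        res = correlation.monte_carlo_correlation(
            a, b, n_datasets=int(config["n_correlation_datasets"]),
            seed=int(seeds["correlation"]),
        )
        corr_records.append(dict(
            pair=protein, r_point=res.r_point, ci_low=res.ci_low,
            ci_high=res.ci_high, significant=res.significant,
            n_datasets=res.n_datasets, seed=res.seed,
        ))
    import pandas as pd

    corr_path = out_dir / "correlations.csv"
    pd.DataFrame.from_records(corr_records).to_csv(corr_path, index=False)

    artifacts = [quant_path, profiles_path, cts_path, expr_path, corr_path]
    manifest = {
        "seeds": seeds,
        "thresholds": config["thresholds"],
        "artifacts": {p.name: _sha256(p) for p in artifacts},
        "n_runs": len(runs),
        "n_quantified": int(quant["fmol_per_ug"].notna().sum()),
        "n_kept": int((quant["decision"] == "kept").sum()),
        "n_flagged": int((quant["decision"] == "flagged").sum()),
        "n_removed": int((quant["decision"] == "removed").sum()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
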