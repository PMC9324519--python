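"""End-to-end synthetic workflow: simulate -> PAS -> screen -> pharm.

``run_pipeline`` executes the full analysis shape on generated data from a
single YAML config, writing every stage's tables plus a manifest that echoes
all parameters and checksums every output, so a rerun with the same config
and seed is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic
from .association_screen import (
    correlation_screen,
    records_to_frame,
    signature_score,
)
from .dependency_pharm import drug_target_correlation, rank_targets
from .pas_engine import count_regulated, pas_table
from .pathway_model import Pathway, PathwayCollection, write_collection

DEFAULTS = {
    "seed": 0,
    "alpha": 0.05,
    "r_min": 0.2,
    "log_base": 10.0,
    "eps": 1e-8,
    "pal_threshold": 0.3,
    "pathway": {"delta": 1.0, "sigma": 0.2, "n_case": 3, "n_ctrl": 3},
    "signatures": {"rho": 0.7, "n_samples": 100, "n_genes_per_sig": 5, "n_sigs": 4},
    "pharm": {"n_lines": 60, "slope": 1.0, "noise_ratio": 0.5},
}


def demo_collection() -> PathwayCollection:
    """Small mixed-role pathway collection used by the shipped demo config."""
    def pw(pid, klass, members):
        return Pathway(id=pid, klass=klass, members=members)

    return PathwayCollection(
        [
            pw("ERK_survival", "signaling",
               {"KIT": 1.0, "MAPK1": 1.0, "MAPK3": 1.0, "DUSP2": -1.0, "MYC": 0.5}),
            pw("ATM_G2M_arrest", "signaling",
               {"ATM": 1.0, "CHEK2": 1.0, "CDC25A": -1.0, "CCNB1": -0.5, "TP53": 0.0}),
            pw("EPO_signaling", "signaling",
               {"EPOR": 1.0, "JAK2": 1.0, "STAT5A": 0.5, "SOCS3": -1.0}),
            pw("glycolysis", "metabolic",
               {"HK2": 1.0, "PFKM": 1.0, "PKM": 1.0, "FBP1": -1.0}),
            pw("oxphos", "metabolic",
               {"NDUFA1": 1.0, "SDHA": 1.0, "COX4I1": 1.0, "UQCRC1": 0.5}),
        ],
        source="paslab demo collection",
    )


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    config = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def validate_config(config: dict) -> None:
    if not 0 < config["alpha"] < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if config["r_min"] < 0:
        raise ValueError("r_min must be >= 0")
    if config["log_base"] <= 1:
        raise ValueError("log_base must be > 1")
    for path_key in ("pathways_file",):
        if path_key in config and not Path(config[path_key]).exists():
            raise FileNotFoundError(config[path_key])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path)


def run_pipeline(config: dict | str, outdir) -> dict:
    """Run simulate -> pas -> screen -> pharm; return the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stage = "simulate"
    try:
        if "pathways_file" in config:
            from .pathway_model import read_collection

            coll = read_collection(config["pathways_file"])
        else:
            coll = demo_collection()
        write_collection(coll, out / "pathways.gmtx")

        pw_cfg = config["pathway"]
        expr, design = synthetic.gen_pathway_dataset(
            coll, activated=config.get("activated", coll.pathways[0].id),
            delta=pw_cfg["delta"], sigma=pw_cfg["sigma"],
            n_case=pw_cfg["n_case"], n_ctrl=pw_cfg["n_ctrl"], seed=seed,
        )
        expr.values.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
        design.rename("group").to_csv(out / "design.tsv", sep="\t", index_label="sample")

        sig_cfg = config["signatures"]
        sigs = {
            f"sig{k}": [f"S{k}_{j}" for j in range(sig_cfg["n_genes_per_sig"])]
            for k in range(sig_cfg["n_sigs"])
        }
        sig_expr = synthetic.gen_signature_dataset(
            sigs, rho=sig_cfg["rho"], n_samples=sig_cfg["n_samples"], seed=seed + 1
        )
        sig_expr.values.to_csv(out / "signature_expression.tsv", sep="\t", index_label="gene")

        ph_cfg = config["pharm"]
        drugs, rnai, crispr = synthetic.gen_pharm_panel(
            n_lines=ph_cfg["n_lines"],
            drug_targets={"imatinib": ["KIT", "ABL1", "PDGFRA"],
                          "sunitinib": ["KIT", "FLT3", "RET"]},
            true_target="KIT", slope=ph_cfg["slope"],
            noise_ratio=ph_cfg["noise_ratio"], seed=seed + 2,
        )

        stage = "pas"
        pas = pas_table(expr, design, coll,
                        log_base=config["log_base"], eps=config["eps"])
        _write_csv(pas.table, out / "pal.csv")
        counts = count_regulated(pas, threshold=config["pal_threshold"])
        counts_df = pd.DataFrame([counts])
        counts_df.insert(0, "threshold", config["pal_threshold"])
        counts_df.to_csv(out / "pal_counts.csv", index=False)

        stage = "screen"
        scores = pd.DataFrame(
            {name: signature_score(sig_expr, genes, name=name)
             for name, genes in sigs.items()}
        ).T
        driver = sig_expr.values.loc["KIT"]
        records, screen_counts = correlation_screen(
            driver, scores, alpha=config["alpha"], r_min=config["r_min"]
        )
        records_to_frame(records).to_csv(out / "screen_records.csv", index=False)
        screen_counts.to_csv(out / "screen_counts.csv")

        stage = "pharm"
        table = drug_target_correlation(drugs, rnai, crispr)
        table.to_csv(out / "drug_target_r.csv")
        ranking = rank_targets(table)
        ranking["target_mean_r"].rename("mean_r").to_csv(out / "target_ranking.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": config,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
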