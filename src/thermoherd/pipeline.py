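"""Pipeline orchestration: run the stages end to end with a provenance
manifest (versions, seed, input checksums, per-stage timings).

Stages: thermal -> pedigree -> genomics -> model -> gibbs -> parameters ->
scan -> enrichment.  When no genotype path is configured the pipeline runs
in degraded pedigree-only mode: the genomics, scan and enrichment stages are
skipped and the model is fitted and solved with A^-1 directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    assign_snps_to_genes,
    enrichment_report,
    fisher_enrichment,
    flag_relevant_genes,
    read_gene_annotation,
    read_gmt,
)
from .gibbs import GibbsConfig
from .model_mme import MMEConfig
from .reaction_norm import HeatStressReactionNormModel
from .scan import EFFECT_LABELS, top_regions
from .thermal import ThermalConfig, daily_thi_table, read_weather

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Run all configured stages; returns (and writes) the manifest.

    Required config keys: ``records``, ``pedigree``, ``weather``,
    ``output_dir``.  Optional: ``genotypes``+``snp_map``, ``genes``,
    ``gene_sets``, ``seed``, ``thi_threshold``, ``at_f``, ``gibbs`` (mapping
    of GibbsConfig fields), ``scan`` ({window_mb, mode, effects}),
    ``enrichment`` ({flank, top_frac, min_parities}).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    thermal = ThermalConfig(thi_threshold=float(config.get("thi_threshold", 68.0)))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "inputs": {},
        "stages": [],
        "assumption_warnings": [
            "G blended with A22 (alpha=%s); construction not uniquely determined by the evaluation design"
            % config.get("blend_alpha", 0.95),
            "window scan mode '%s'" % config.get("scan", {}).get("mode", "sliding"),
            "gene universe = SNP-covered genes",
        ],
    }
    for key in ("records", "pedigree", "weather", "genotypes", "snp_map", "genes", "gene_sets"):
        if key in config and config[key] is not None:
            manifest["inputs"][key] = {"path": str(config[key]), "sha256": _sha256(config[key])}

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.time()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                entry = {"name": name, "seconds": round(time.time() - self.t0, 3)}
                if exc_type is not None:
                    entry["status"] = "failed"
                    entry["error"] = f"{exc_type.__name__}: {exc}"
                    manifest["stages"].append(entry)
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline aborted in stage '{name}': {exc}") from exc
                entry["status"] = "ok"
                manifest["stages"].append(entry)
                return False

        return _Stage()

    genomic = "genotypes" in config and config["genotypes"] is not None
    if not genomic:
        logger.warning("no genotype path configured: running degraded pedigree-only pipeline")

    with stage("thermal"):
        weather = read_weather(config["weather"])
        daily = daily_thi_table(weather, thermal)
        daily.to_csv(out_dir / "thi_daily.csv", index=False)

    with stage("model_build"):
        model = HeatStressReactionNormModel.from_files(
            config["records"],
            config["pedigree"],
            config["weather"],
            genotype_tsv=config.get("genotypes"),
            snp_map_tsv=config.get("snp_map"),
            thermal=thermal,
            mme_config=MMEConfig(),
            binary_outcome=bool(config.get("binary_outcome", True)),
        )
        if model.qc_report is not None:
            model.qc_report.to_frame().to_csv(out_dir / "snp_qc.tsv", sep="\t", index=False)

    with stage("gibbs"):
        gcfg = GibbsConfig(**{"seed": seed, **config.get("gibbs", {})})
        results = model.fit(gcfg)
        results.chain.to_frame().to_csv(out_dir / "chain.tsv", sep="\t", index=False)
        results.diagnostics(plot_path=out_dir / "trace.png").to_csv(
            out_dir / "diagnostics.tsv", sep="\t", index=False
        )

    with stage("parameters"):
        at_f = float(config.get("at_f", 10.0))
        results.parameter_table(f=at_f).to_csv(out_dir / "parameters.tsv", sep="\t", index=False)
        with open(out_dir / "summary.txt", "w") as fh:
            fh.write(results.summary(f=at_f))

    with stage("solve"):
        solution = results.solve(genomic=genomic)
        solution.breeding_values.to_frame().to_csv(out_dir / "breeding_values.tsv", sep="\t", index=False)

    slope_effects = {}
    if genomic:
        with stage("scan"):
            scfg = config.get("scan", {})
            effects = scfg.get("effects", list(EFFECT_LABELS))
            window_mb = float(scfg.get("window_mb", 2.0))
            mode = scfg.get("mode", "sliding")
            scans = []
            for eff in effects:
                se = solution.snp_effects(eff)
                if eff.startswith("v"):
                    slope_effects[int(eff[1])] = se.values
                scans.append(solution.window_scan(eff, window_mb=window_mb, mode=mode))
            windows = pd.concat(scans, ignore_index=True)
            windows.to_csv(out_dir / "windows.tsv", sep="\t", index=False)
            top_regions(windows, 20).to_csv(out_dir / "top_regions.tsv", sep="\t", index=False)

        if "genes" in config and "gene_sets" in config:
            with stage("enrichment"):
                ecfg = config.get("enrichment", {})
                genes = read_gene_annotation(config["genes"])
                sets = read_gmt(config["gene_sets"])
                snp_gene = assign_snps_to_genes(
                    model.genotypes.snp_map, genes, flank=int(ecfg.get("flank", 15_000))
                )
                background = set(snp_gene["gene_id"].unique())
                relevant = flag_relevant_genes(
                    slope_effects,
                    snp_gene,
                    top_frac=float(ecfg.get("top_frac", 0.05)),
                    min_parities=int(ecfg.get("min_parities", 2)),
                )
                report = enrichment_report(
                    fisher_enrichment(relevant, background, sets),
                    adjust=ecfg.get("adjust", "none"),
                )
                report.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
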