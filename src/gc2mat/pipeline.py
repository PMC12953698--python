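"""End-to-end orchestration over simulated or loaded inputs.

``run_pipeline`` executes the stages in dependency order — simulate (or
load) -> filter/DE per knockdown genotype -> overlaps -> TE -> stage
signature -> TOP -> chromatin marks -> reports — and records a manifest with
parameters, seeds and output checksums so a rerun with the same
configuration can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, de, genesets, signature, simulate, te, topmotif
from .simulate import CONTROL_GENOTYPE, SimulationConfig

logger = logging.getLogger("gc2mat")


@dataclass
class PipelineConfig:
    """Validated configuration of a full run."""

    out_dir: str = "gc2mat_out"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "de", "overlap", "te", "signature", "top", "marks",
    )
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    fdr_threshold: float = 0.05
    fc_mode: str = "fold2"
    te_alpha: float = 0.05
    te_use_fdr: bool = False
    overlap_iterations: int = 1_000_000
    min_run: int = 5
    profile_ratio: float = 2.0
    lfc_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimulationConfig(seed=raw.get("seed", 0), **sim_raw)
        cfg.sim.seed = cfg.seed
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    All outputs are TSV/JSON under ``cfg.out_dir``; the manifest
    (``manifest.json``) lists per-stage parameters and output checksums.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.sim.seed = cfg.seed
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("sim",)
        },
        "sim": dataclasses.asdict(cfg.sim),
        "stages": [],
    }
    summary: dict = {}
    outputs: list[Path] = []

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "status": "completed",
                "outputs": {str(f.name): _sha256(f) for f in files},
            }
        )
        outputs.extend(files)
        logger.info("stage %s completed (%d outputs)", stage, len(files))

    # ------------------------------------------------------------ simulate
    counts, bulk_truth = simulate.simulate_bulk_counts(cfg.sim)
    if "simulate" in cfg.stages:
        counts_path = out / "counts.tsv"
        meta_path = out / "meta.tsv"
        truth_path = out / "ground_truth_bulk.tsv"
        counts.write_tsv(counts_path, meta_path)
        bulk_truth.write_tsv(truth_path)
        record("simulate", [counts_path, meta_path, truth_path])

    # ------------------------------------------------------------ DE
    de_tables: dict[str, pd.DataFrame] = {}
    if "de" in cfg.stages:
        files = []
        de_cfg = de.DEConfig(
            fdr_threshold=cfg.fdr_threshold, log2fc_mode=cfg.fc_mode
        )
        de_summary = {}
        for genotype in cfg.sim.genotypes:
            table = de.run_de_comparison(counts, genotype, CONTROL_GENOTYPE, de_cfg)
            _, counts_summary = de.classify_de(table, de_cfg)
            de_tables[genotype] = table
            path = out / f"de_{genotype}.tsv"
            table.to_csv(path, sep="\t", index=False)
            files.append(path)
            de_summary[genotype] = counts_summary
        summary["de"] = de_summary
        record("de", files)

    # ------------------------------------------------------------ overlap
    if "overlap" in cfg.stages and de_tables:
        sets = [
            genesets.GeneSet(
                gt, table.loc[table["class"] == "up", "gene_id"].tolist()
            )
            for gt, table in de_tables.items()
        ]
        universe = genesets.GeneSet(
            "tested",
            next(iter(de_tables.values()))
            .loc[lambda t: t["class"] != "filtered", "gene_id"]
            .tolist(),
        )
        result = genesets.overlap_randomization_test(
            sets, universe, n_iter=cfg.overlap_iterations, seed=cfg.seed
        )
        venn = genesets.overlap_fraction_summary(sets)
        overlap_out = {
            "observed_intersection": result.observed_intersection,
            "n_iterations": result.n_iterations,
            "n_exceedances": result.n_exceedances,
            "empirical_p": result.empirical_p,
            "shared_fraction": result.shared_fraction,
            "venn": venn,
        }
        path = out / "overlap.json"
        path.write_text(json.dumps(overlap_out, indent=2, default=str))
        summary["overlap"] = {
            "observed_intersection": result.observed_intersection,
            "empirical_p": result.empirical_p,
        }
        record("overlap", [path])

    # ------------------------------------------------------------ TE
    if "te" in cfg.stages:
        te_counts, te_truth = simulate.simulate_polysome_experiment(cfg.sim)
        design = te.build_te_design(te_counts, CONTROL_GENOTYPE, "zfrp8_GKD")
        table = te.run_te_analysis(
            te_counts, design, alpha=cfg.te_alpha, use_fdr=cfg.te_use_fdr
        )
        path = out / "te.tsv"
        truth_path = out / "ground_truth_te.tsv"
        table.to_csv(path, sep="\t", index=False)
        te_truth.write_tsv(truth_path)
        summary["te"] = te.classify_te(table)
        record("te", [path, truth_path])

    # ------------------------------------------------------------ signature
    if "signature" in cfg.stages:
        stage_table, stage_truth = simulate.simulate_stage_tpm(cfg.sim)
        profiles = signature.classify_stage_profiles(
            stage_table, ratio=cfg.profile_ratio
        )
        path = out / "stage_profiles.tsv"
        truth_path = out / "ground_truth_stages.tsv"
        profiles.to_csv(path, sep="\t", index=False)
        stage_truth.write_tsv(truth_path)
        summary["signature"] = (
            profiles["profile"].value_counts().to_dict()
        )
        record("signature", [path, truth_path])

    # ------------------------------------------------------------ TOP
    if "top" in cfg.stages:
        profiles_cage, contigs, top_truth = simulate.simulate_cage_utrs(cfg.sim)
        calls = []
        for prof in profiles_cage:
            call = topmotif.call_top_from_cage(
                prof, contigs[prof.transcript_id], min_run=cfg.min_run
            )
            calls.append(
                {
                    "gene_id": call.transcript_id,
                    "tss": call.tss_position,
                    "first_base": call.first_base,
                    "run_length": call.pyrimidine_run_length,
                    "is_top": call.is_top,
                }
            )
        calls_df = pd.DataFrame(calls)
        path = out / "top_calls.tsv"
        truth_path = out / "ground_truth_top.tsv"
        calls_df.to_csv(path, sep="\t", index=False)
        top_truth.write_tsv(truth_path)
        summary["top"] = {
            "n_top": int(calls_df["is_top"].sum()),
            "n_transcripts": len(calls_df),
        }
        record("top", [path, truth_path])

    # ------------------------------------------------------------ marks
    if "marks" in cfg.stages:
        wt, kd, genes, tads, marks_truth = simulate.simulate_marks_and_tads(cfg.sim)
        wt_q = chromatin.quantify_gene_marks(chromatin.rpkm_bin_track(wt), genes)
        kd_q = chromatin.quantify_gene_marks(chromatin.rpkm_bin_track(kd), genes)
        calls = chromatin.differential_mark_call(
            wt_q, kd_q, lfc_threshold=cfg.lfc_threshold
        )
        redis = chromatin.redistribution_summary(
            chromatin.binarize_track(wt), chromatin.binarize_track(kd)
        )
        path = out / "mark_calls.tsv"
        truth_path = out / "ground_truth_marks.tsv"
        calls.to_csv(path, sep="\t", index=False)
        marks_truth.write_tsv(truth_path)
        redis_path = out / "redistribution.json"
        redis_path.write_text(json.dumps(redis, indent=2))
        summary["marks"] = {
            "calls": calls["call"].value_counts().to_dict(),
            **redis,
        }
        record("marks", [path, truth_path, redis_path])

    # ------------------------------------------------------------ reports
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=str))
    record("reports", [summary_path])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def write_reports(results: dict, out_dir: str | Path) -> Path:
    """Write a summary JSON bundle from stage-level result dictionaries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "summary.json"
    path.write_text(json.dumps(results, indent=2, default=str))
    return path
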