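"""Bulk RNA-seq differential expression.

Each knockdown genotype is tested independently against the shared control:
low-count filtering (total reads across all samples below a threshold),
median-of-ratios normalization, a per-gene NB Wald test of case vs control,
BH adjustment over the tested genes, and up/down classification.

Two fold-change conventions are supported because both appear in practice:
``fold2`` calls a gene significant at |log2FC| >= 1 (a twofold change) and
``log2fc2`` at |log2FC| >= 2 (a fourfold change).  The mode in force is
recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nbglm
from .countmatrix import CountMatrix

FC_MODES = ("fold2", "log2fc2")


@dataclass
class DEConfig:
    """Filtering and significance thresholds for the DE stage."""

    min_total_reads: int = 5
    fdr_threshold: float = 0.05
    log2fc_mode: str = "fold2"

    def __post_init__(self) -> None:
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be non-negative")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.log2fc_mode not in FC_MODES:
            raise ValueError(f"log2fc_mode must be one of {FC_MODES}")

    @property
    def log2fc_cut(self) -> float:
        return 1.0 if self.log2fc_mode == "fold2" else 2.0


def filter_low_counts(
    counts: CountMatrix, min_total: int = 5
) -> tuple[CountMatrix, list[str]]:
    """Remove genes with fewer than ``min_total`` reads summed over all samples.

    Returns the filtered matrix and the list of removed gene ids.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    totals = counts.counts.sum(axis=1)
    keep = [g for g, t in zip(counts.gene_ids, totals) if t >= min_total]
    removed = [g for g, t in zip(counts.gene_ids, totals) if t < min_total]
    return counts.subset_genes(keep), removed


def classify_de(table: pd.DataFrame, cfg: DEConfig) -> tuple[pd.DataFrame, dict]:
    """Assign up/down/ns/filtered classes and return summary counts."""
    table = table.copy()
    sig = (table["fdr"] < cfg.fdr_threshold) & (
        table["log2fc"].abs() >= cfg.log2fc_cut
    )
    cls = np.where(
        table["pvalue"].isna(),
        "filtered",
        np.where(sig & (table["log2fc"] > 0), "up",
                 np.where(sig & (table["log2fc"] < 0), "down", "ns")),
    )
    table["class"] = cls
    summary = {
        "n_up": int((cls == "up").sum()),
        "n_down": int((cls == "down").sum()),
        "n_ns": int((cls == "ns").sum()),
        "n_filtered": int((cls == "filtered").sum()),
    }
    return table, summary


def run_de_comparison(
    counts: CountMatrix,
    case: str,
    control: str,
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """Test one knockdown genotype against the control genotype.

    The returned table covers every input gene: genes failing the low-count
    filter carry class ``filtered`` and NaN statistics.  ``log2fc`` is
    positive when the case genotype is higher.
    """
    cfg = cfg or DEConfig()
    case_samples = counts.samples_with(genotype=case)
    control_samples = counts.samples_with(genotype=control)
    if not case_samples:
        raise ValueError(f"genotype label not found: {case!r}")
    if not control_samples:
        raise ValueError(f"genotype label not found: {control!r}")
    if len(case_samples) < 2 or len(control_samples) < 2:
        warnings.warn("fewer than 2 replicates in a group; tests will be unstable")

    sub = counts.subset_samples(control_samples + case_samples)
    filtered, removed = filter_low_counts(sub, cfg.min_total_reads)

    labels = ["control" if s in control_samples else "case" for s in sub.sample_ids]
    design = nbglm.one_hot_design(labels, level_order=["control", "case"])
    norm = nbglm.estimate_size_factors(filtered)
    disp = nbglm.estimate_dispersions(filtered, design, norm)
    fit = nbglm.fit_nb_glm(filtered, design, norm, disp)
    contrast = np.array([-1.0, 1.0])  # case - control
    table = nbglm.wald_test(fit, contrast)
    table, _ = classify_de(table, cfg)

    if removed:
        pad = pd.DataFrame(
            {
                "gene_id": removed,
                "log2fc": np.nan,
                "stat": np.nan,
                "pvalue": np.nan,
                "fdr": np.nan,
                "class": "filtered",
            }
        )
        table = pd.concat([table, pad], ignore_index=True)
    order = {g: i for i, g in enumerate(counts.gene_ids)}
    table = table.sort_values("gene_id", key=lambda s: s.map(order)).reset_index(
        drop=True
    )
    table.attrs["fc_mode"] = cfg.log2fc_mode
    return table
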