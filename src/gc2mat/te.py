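"""Polysome-seq differential translational efficiency.

Samples from a polysome-profiling experiment fall into four conditions,
genotype x RNA fraction: WT_Input, KO_Input, WT_Polysomes, KO_Polysomes.
Translational efficiency (TE) is the polysome-to-input representation of a
transcript; the genotype effect on TE is the interaction contrast

    (KO_Polysomes - KO_Input) - (WT_Polysomes - WT_Input)

on the log scale, which cancels transcription-level changes and any
fraction-wide scaling.  The stage runs TMM normalization, empirical-Bayes
dispersion estimation, NB GLM fitting and a likelihood-ratio test of the
contrast; classification defaults to raw p < alpha on the sign of the TE
change, with an option to classify on BH-adjusted values instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nbglm
from .countmatrix import CountMatrix
from .de import filter_low_counts

CONDITIONS = ("WT_Input", "KO_Input", "WT_Polysomes", "KO_Polysomes")
# contrast on condition means (a, b, c, d) = (WT_I, KO_I, WT_P, KO_P):
# (d - b) - (c - a)
TE_CONTRAST = np.array([1.0, -1.0, -1.0, 1.0])


@dataclass
class TEDesign:
    """Four-condition design with the TE interaction contrast."""

    sample_ids: list[str]
    conditions: list[str]  # per sample, drawn from CONDITIONS
    design: nbglm.Design = field(init=False)
    contrast: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        missing = [c for c in CONDITIONS if c not in self.conditions]
        if missing:
            raise ValueError(f"missing conditions: {missing}")
        self.design = nbglm.one_hot_design(
            self.conditions, level_order=list(CONDITIONS)
        )
        self.contrast = TE_CONTRAST.copy()


def build_te_design(
    counts: CountMatrix, wt: str, ko: str
) -> TEDesign:
    """Map (genotype, fraction) metadata onto the four-condition design."""
    conditions = []
    sample_ids = []
    for s in counts.sample_ids:
        info = counts.metadata[s]
        if info.genotype == wt and info.fraction == "input":
            cond = "WT_Input"
        elif info.genotype == ko and info.fraction == "input":
            cond = "KO_Input"
        elif info.genotype == wt and info.fraction == "polysome":
            cond = "WT_Polysomes"
        elif info.genotype == ko and info.fraction == "polysome":
            cond = "KO_Polysomes"
        else:
            continue
        conditions.append(cond)
        sample_ids.append(s)
    return TEDesign(sample_ids=sample_ids, conditions=conditions)


def run_te_analysis(
    counts: CountMatrix,
    design: TEDesign,
    alpha: float = 0.05,
    min_total_reads: int = 5,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """LRT-based differential TE over the four-condition design.

    Returns a table with ``delta_te_log2`` (the contrast estimate in log2
    units), the LRT statistic, raw p, BH fdr, and a class in
    {te_up, te_down, ns, filtered}.  Classification uses raw p by default;
    ``use_fdr=True`` classifies on the BH-adjusted column instead.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sub = counts.subset_samples(design.sample_ids)
    filtered, removed = filter_low_counts(sub, min_total_reads)
    norm = nbglm.estimate_tmm_factors(filtered)
    disp = nbglm.estimate_dispersions(filtered, design.design, norm)
    table = nbglm.lrt_contrast_test(
        filtered, design.design, norm, disp, design.contrast
    )
    table = table.rename(columns={"log2fc": "delta_te_log2"})
    crit = table["fdr"] if use_fdr else table["pvalue"]
    sig = crit < alpha
    table["class"] = np.where(
        table["pvalue"].isna(),
        "filtered",
        np.where(sig & (table["delta_te_log2"] > 0), "te_up",
                 np.where(sig & (table["delta_te_log2"] < 0), "te_down", "ns")),
    )
    if removed:
        pad = pd.DataFrame(
            {
                "gene_id": removed,
                "delta_te_log2": np.nan,
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
    table.attrs["alpha"] = alpha
    table.attrs["use_fdr"] = use_fdr
    return table


def classify_te(result: pd.DataFrame) -> dict:
    """Summary counts of translationally up/down transcripts."""
    cls = result["class"]
    return {
        "n_te_up": int((cls == "te_up").sum()),
        "n_te_down": int((cls == "te_down").sum()),
        "n_ns": int((cls == "ns").sum()),
        "n_filtered": int((cls == "filtered").sum()),
    }
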