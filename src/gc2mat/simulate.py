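"""Synthetic data with recorded ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume:
NB-distributed bulk counts with knockdown effects on a "germ cell gene"
cohort and a maternal cohort; a four-condition polysome experiment with
planted translational-efficiency shifts; stage-graded TPM profiles;
TOP / non-TOP 5' termini with peaked CAGE profiles; and promoter-peaked
histone-mark tracks with designed gain/loss over TAD-embedded genes.

Every generator is a pure function of its configuration (the seed included):
identical inputs give identical outputs.  The ground-truth record carries the
designed effects so downstream recovery can be scored without re-reading the
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin import BinnedTrack, GeneIntervals, TadSet
from .countmatrix import CountMatrix, SampleInfo
from .signature import STAGES, StageExpressionTable
from .topmotif import CageProfile

CONTROL_GENOTYPE = "nosGAL4"
KD_GENOTYPES = ("zfrp8_GKD", "mio_GKD", "raptor_GKD")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, defaulting to the study conditions.

    Baseline gene means are log-normal with median ``baseline_median`` reads;
    counts are NB with variance ``mu + dispersion * mu**2``; two biological
    replicates per condition mirror the sequenced designs.
    """

    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 2
    baseline_median: float = 500.0
    baseline_sdlog: float = 1.0
    dispersion: float = 0.05

    # bulk RNA-seq effects
    germ_cell_cohort_size: int = 100
    germ_cell_log2fc: float = 2.0  # up in knockdowns
    maternal_cohort_size: int = 100
    maternal_log2fc: float = -2.0  # down in knockdowns
    private_up_size: int = 50  # per-genotype extra upregulated genes
    genotypes: tuple[str, ...] = KD_GENOTYPES

    # polysome experiment
    te_cohort_size: int = 100
    delta_te_log2: float = 2.0
    te_down_fraction: float = 0.5
    te_base_sd: float = 0.25  # per-gene baseline TE spread (log2)
    polysome_scale: float = 1.5  # fraction-wide library scaling

    # stage TPM profiles
    stage_fold: float = 8.0
    stage_tpm_median: float = 50.0

    # CAGE / TOP
    n_transcripts: int = 60
    top_fraction: float = 0.5
    top_run_min: int = 5
    top_run_max: int = 14
    cage_reads: int = 200
    cage_window: int = 50

    # chromatin marks
    bin_width: int = 100
    chrom_length: int = 1_000_000
    background_rate: float = 2.0
    peak_height: float = 20.0
    kd_reduction: float = 4.0
    n_mark_genes: int = 300
    loss_cohort_size: int = 100
    gain_cohort_size: int = 100
    stable_peak_size: int = 50
    n_tads: int = 20
    tad_size_range: tuple[int, int] = (20_000, 50_000)

    def __post_init__(self) -> None:
        if self.germ_cell_cohort_size + self.maternal_cohort_size > self.n_genes:
            raise ValueError("cohorts exceed gene count")
        if self.te_cohort_size > self.n_genes:
            raise ValueError("TE cohort exceeds gene count")
        if not 0 <= self.top_fraction <= 1:
            raise ValueError("top_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-gene record of the designed effects."""

    table: pd.DataFrame

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson NB sampler with Var = mu + alpha mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


# --------------------------------------------------------------------------
# bulk RNA-seq
# --------------------------------------------------------------------------


def simulate_bulk_counts(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Control + knockdown bulk libraries with cohort fold changes.

    A shared germ-cell cohort goes up and a maternal cohort goes down in
    every knockdown genotype; each genotype additionally upregulates a
    private cohort, so multiple-genotype overlaps have designed structure.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    baseline = np.exp(
        rng.normal(np.log(cfg.baseline_median), cfg.baseline_sdlog, cfg.n_genes)
    )

    perm = rng.permutation(cfg.n_genes)
    germ = perm[: cfg.germ_cell_cohort_size]
    maternal = perm[
        cfg.germ_cell_cohort_size : cfg.germ_cell_cohort_size + cfg.maternal_cohort_size
    ]
    cursor = cfg.germ_cell_cohort_size + cfg.maternal_cohort_size
    private: dict[str, np.ndarray] = {}
    for gt in cfg.genotypes:
        private[gt] = perm[cursor : cursor + cfg.private_up_size]
        cursor += cfg.private_up_size

    log2fc = {gt: np.zeros(cfg.n_genes) for gt in cfg.genotypes}
    for gt in cfg.genotypes:
        log2fc[gt][germ] = cfg.germ_cell_log2fc
        log2fc[gt][maternal] = cfg.maternal_log2fc
        log2fc[gt][private[gt]] = cfg.germ_cell_log2fc

    sample_ids: list[str] = []
    metadata: dict[str, SampleInfo] = {}
    columns = []
    for gt in (CONTROL_GENOTYPE, *cfg.genotypes):
        for r in range(1, cfg.n_replicates + 1):
            sid = f"{gt}_rep{r}"
            sample_ids.append(sid)
            metadata[sid] = SampleInfo(sample_id=sid, genotype=gt, replicate=r)
            mu = baseline * (
                2.0 ** log2fc[gt] if gt != CONTROL_GENOTYPE else 1.0
            )
            columns.append(_nb_draw(rng, mu, cfg.dispersion))
    counts = np.column_stack(columns)

    cohort = np.array(["none"] * cfg.n_genes, dtype=object)
    cohort[germ] = "germ_cell"
    cohort[maternal] = "maternal"
    for gt in cfg.genotypes:
        cohort[private[gt]] = f"private_{gt}"
    truth = pd.DataFrame({"gene_id": gene_ids, "cohort": cohort})
    for gt in cfg.genotypes:
        truth[f"true_log2fc_{gt}"] = log2fc[gt]

    return (
        CountMatrix(gene_ids, sample_ids, counts, metadata),
        GroundTruth(truth),
    )


# --------------------------------------------------------------------------
# polysome experiment
# --------------------------------------------------------------------------


def simulate_polysome_experiment(
    cfg: SimulationConfig, wt: str = CONTROL_GENOTYPE, ko: str = "zfrp8_GKD"
) -> tuple[CountMatrix, GroundTruth]:
    """Four-condition polysome-seq counts with planted TE shifts.

    Polysome means are input means times ``2**(te_base + delta_te * KO)``,
    scaled fraction-wide by ``polysome_scale`` so TMM normalization is
    actually exercised.  A ``te_down_fraction`` of the TE cohort gets the
    negative effect.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    baseline = np.exp(
        rng.normal(np.log(cfg.baseline_median), cfg.baseline_sdlog, cfg.n_genes)
    )
    te_base = rng.normal(0.0, cfg.te_base_sd, cfg.n_genes)

    perm = rng.permutation(cfg.n_genes)
    cohort_idx = perm[: cfg.te_cohort_size]
    n_down = int(round(cfg.te_cohort_size * cfg.te_down_fraction))
    delta = np.zeros(cfg.n_genes)
    delta[cohort_idx[:n_down]] = -cfg.delta_te_log2
    delta[cohort_idx[n_down:]] = cfg.delta_te_log2

    sample_ids: list[str] = []
    metadata: dict[str, SampleInfo] = {}
    columns = []
    for genotype, fraction in (
        (wt, "input"),
        (ko, "input"),
        (wt, "polysome"),
        (ko, "polysome"),
    ):
        for r in range(1, cfg.n_replicates + 1):
            sid = f"{genotype}_{fraction}_rep{r}"
            sample_ids.append(sid)
            metadata[sid] = SampleInfo(
                sample_id=sid, genotype=genotype, fraction=fraction, replicate=r
            )
            mu = baseline.copy()
            if fraction == "polysome":
                te = te_base + (delta if genotype == ko else 0.0)
                mu = mu * (2.0**te) * cfg.polysome_scale
            columns.append(_nb_draw(rng, mu, cfg.dispersion))
    counts = np.column_stack(columns)

    cohort = np.array(["none"] * cfg.n_genes, dtype=object)
    cohort[cohort_idx[:n_down]] = "te_down"
    cohort[cohort_idx[n_down:]] = "te_up"
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "cohort": cohort,
            "true_delta_te_log2": delta,
            "te_base_log2": te_base,
        }
    )
    return CountMatrix(gene_ids, sample_ids, counts, metadata), GroundTruth(truth)


# --------------------------------------------------------------------------
# stage-graded TPM
# --------------------------------------------------------------------------


def simulate_stage_tpm(
    cfg: SimulationConfig,
) -> tuple[StageExpressionTable, GroundTruth]:
    """Stage-enriched TPM profiles with planted germ-cell-like and
    maternal-like cohorts.

    Germ-cell-like genes are expressed through GSC/CB/cyst and reduced
    ``stage_fold``-fold in whole ovaries; maternal-like genes are reversed.
    Values carry NB noise around the designed stage means.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    base = np.exp(
        rng.normal(np.log(cfg.stage_tpm_median), cfg.baseline_sdlog, cfg.n_genes)
    )
    perm = rng.permutation(cfg.n_genes)
    germ = perm[: cfg.germ_cell_cohort_size]
    maternal = perm[
        cfg.germ_cell_cohort_size : cfg.germ_cell_cohort_size + cfg.maternal_cohort_size
    ]

    tpm = np.empty((cfg.n_genes, len(STAGES)))
    for j, stage in enumerate(STAGES):
        mu = base.copy()
        if stage == "whole_ovary":
            mu[germ] = mu[germ] / cfg.stage_fold
        else:
            mu[maternal] = mu[maternal] / cfg.stage_fold
        tpm[:, j] = _nb_draw(rng, mu, cfg.dispersion).astype(float)

    cohort = np.array(["none"] * cfg.n_genes, dtype=object)
    cohort[germ] = "germ_cell_like"
    cohort[maternal] = "maternal_like"
    truth = pd.DataFrame({"gene_id": gene_ids, "true_profile": cohort})
    table = StageExpressionTable(
        gene_ids=gene_ids,
        library_ids=list(STAGES),
        groups=list(STAGES),
        tpm=tpm,
    )
    return table, GroundTruth(truth)


# --------------------------------------------------------------------------
# CAGE profiles and 5' leaders
# --------------------------------------------------------------------------

_PURINES = "AG"
_PYRIMIDINES = "CT"
_BASES = "ACGT"


def simulate_cage_utrs(
    cfg: SimulationConfig,
) -> tuple[list[CageProfile], dict[str, str], GroundTruth]:
    """Per-transcript contigs, CAGE 5'-end profiles and planted TOP leaders.

    Each transcript lives on its own contig; the planted TSS sits mid-contig
    and the CAGE profile is a multinomial sharply peaked there.  TOP leaders
    start with C and run 5-14 pyrimidines before a purine; non-TOP leaders
    start with a purine or carry a sub-threshold run.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    contig_len = 2 * cfg.cage_window + 20
    tss_plus = contig_len // 2

    profiles: list[CageProfile] = []
    contigs: dict[str, str] = {}
    rows = []
    n_top = int(round(cfg.n_transcripts * cfg.top_fraction))
    for t in range(cfg.n_transcripts):
        tx = f"tx{t:04d}"
        is_top = t < n_top
        strand = "+" if t % 2 == 0 else "-"
        leader_len = 30
        if is_top:
            run = int(rng.integers(cfg.top_run_min, cfg.top_run_max + 1))
            leader = "C" + "".join(rng.choice(list(_PYRIMIDINES), run - 1))
            leader += rng.choice(list(_PURINES))
            leader += "".join(rng.choice(list(_BASES), leader_len - len(leader)))
        else:
            if t % 3 == 0:
                # pyrimidine start but short run
                run = int(rng.integers(1, cfg.top_run_min - 1 + 1))
                leader = "C" + "".join(rng.choice(list(_PYRIMIDINES), run - 1))
                leader += rng.choice(list(_PURINES))
            else:
                leader = rng.choice(list(_PURINES))
            leader += "".join(rng.choice(list(_BASES), leader_len - len(leader)))
        upstream = "".join(rng.choice(list(_BASES), tss_plus))
        downstream = "".join(
            rng.choice(list(_BASES), contig_len - tss_plus - leader_len)
        )
        seq_plus = upstream + leader + downstream  # leader starts at tss_plus

        if strand == "+":
            contig = seq_plus
            tss = tss_plus
        else:
            contig = _revcomp(seq_plus)
            tss = contig_len - 1 - tss_plus

        # peaked CAGE profile: most mass at the TSS, light shoulders
        offsets = np.arange(-3, 4)
        weights = np.array([1, 2, 5, 80, 5, 2, 1], dtype=float)
        draw = rng.multinomial(cfg.cage_reads, weights / weights.sum())
        step = 1 if strand == "+" else -1
        counts = {int(tss + step * o): int(c) for o, c in zip(offsets, draw) if c > 0}
        profiles.append(CageProfile(transcript_id=tx, strand=strand, counts=counts))
        contigs[tx] = contig
        rows.append(
            {
                "gene_id": tx,
                "strand": strand,
                "true_tss": tss,
                "is_top": is_top,
                "leader": leader,
            }
        )
    return profiles, contigs, GroundTruth(pd.DataFrame(rows))


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# chromatin marks and TADs
# --------------------------------------------------------------------------


def simulate_marks_and_tads(
    cfg: SimulationConfig,
) -> tuple[BinnedTrack, BinnedTrack, GeneIntervals, TadSet, GroundTruth]:
    """WT and knockdown mark tracks with designed promoter gain/loss.

    Genes are laid on one chromosome; the loss cohort carries a WT promoter
    peak reduced ``kd_reduction``-fold in the knockdown, the gain cohort the
    mirror image, a stable cohort keeps its peak, and the rest sit at
    background.  Poisson noise throughout.  TADs are non-overlapping random
    intervals.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    chrom = "chr2L"
    n_bins = cfg.chrom_length // cfg.bin_width

    gene_len = 2000
    spacing = cfg.chrom_length // (cfg.n_mark_genes + 2)
    starts = np.array(
        [spacing * (i + 1) for i in range(cfg.n_mark_genes)], dtype=int
    )
    strands = np.where(rng.random(cfg.n_mark_genes) < 0.5, "+", "-")
    genes = GeneIntervals(
        pd.DataFrame(
            {
                "gene_id": [f"g{i:05d}" for i in range(cfg.n_mark_genes)],
                "chrom": chrom,
                "start": starts,
                "end": starts + gene_len,
                "strand": strands,
            }
        )
    )

    order = rng.permutation(cfg.n_mark_genes)
    loss = order[: cfg.loss_cohort_size]
    gain = order[cfg.loss_cohort_size : cfg.loss_cohort_size + cfg.gain_cohort_size]
    stable = order[
        cfg.loss_cohort_size
        + cfg.gain_cohort_size : cfg.loss_cohort_size
        + cfg.gain_cohort_size
        + cfg.stable_peak_size
    ]

    wt_mu = np.full(n_bins, cfg.background_rate)
    kd_mu = np.full(n_bins, cfg.background_rate)
    tss = genes.tss()
    promoter_bins = 500 // cfg.bin_width
    loss_set, gain_set, stable_set = set(loss), set(gain), set(stable)
    for i in range(cfg.n_mark_genes):
        b = int(tss[i]) // cfg.bin_width
        lo, hi = max(b - promoter_bins, 0), min(b + promoter_bins + 1, n_bins)
        if i in loss_set:
            wt_mu[lo:hi] += cfg.peak_height
            kd_mu[lo:hi] += cfg.peak_height / cfg.kd_reduction
        elif i in gain_set:
            kd_mu[lo:hi] += cfg.peak_height
            wt_mu[lo:hi] += cfg.peak_height / cfg.kd_reduction
        elif i in stable_set:
            wt_mu[lo:hi] += cfg.peak_height
            kd_mu[lo:hi] += cfg.peak_height

    wt = BinnedTrack(
        bin_width=cfg.bin_width, signal={chrom: rng.poisson(wt_mu).astype(float)}
    )
    kd = BinnedTrack(
        bin_width=cfg.bin_width, signal={chrom: rng.poisson(kd_mu).astype(float)}
    )

    # non-overlapping TADs
    tad_rows = []
    cursor = int(rng.integers(0, 10_000))
    for _ in range(cfg.n_tads):
        size = int(rng.integers(*cfg.tad_size_range))
        if cursor + size > cfg.chrom_length:
            break
        tad_rows.append({"chrom": chrom, "start": cursor, "end": cursor + size})
        cursor += size + int(rng.integers(1_000, 10_000))
    tads = TadSet(pd.DataFrame(tad_rows))

    mark_class = np.array(["background"] * cfg.n_mark_genes, dtype=object)
    mark_class[loss] = "loss"
    mark_class[gain] = "gain"
    mark_class[stable] = "stable"
    truth = GroundTruth(
        pd.DataFrame(
            {
                "gene_id": genes.table["gene_id"],
                "true_mark_class": mark_class,
            }
        )
    )
    return wt, kd, genes, tads, truth
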