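"""Binned chromatin-mark quantification and differential summaries.

Works on regularly binned signal tracks (CUT&RUN-style coverage of repressive
histone marks such as H3K9me3/H3K27me3): RPKM normalization, Poisson
binarization, strand-aware promoter/gene-body quantification, gain/loss calls
between a wild-type and a knockdown track, a genome-wide redistribution
summary, and scaled meta-region matrices over genes or topologically
associating domains (TADs) with fixed flanks.

All coordinates are 0-based half-open; tracks tile each chromosome with
contiguous fixed-width bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BinnedTrack:
    """Fixed-width binned signal over one or more chromosomes."""

    bin_width: int
    signal: dict[str, np.ndarray]  # chrom -> per-bin values
    normalization: str = "raw"  # "raw" | "rpkm"
    total_reads: int = 0

    def __post_init__(self) -> None:
        self.signal = {c: np.asarray(v, dtype=float) for c, v in self.signal.items()}
        for c, v in self.signal.items():
            if np.any(v < 0):
                raise ValueError(f"negative signal on {c}")
        if self.total_reads == 0 and self.normalization == "raw":
            self.total_reads = int(round(sum(v.sum() for v in self.signal.values())))

    def chrom_length(self, chrom: str) -> int:
        return len(self.signal[chrom]) * self.bin_width

    def n_bins(self) -> int:
        return sum(len(v) for v in self.signal.values())

    def same_binning(self, other: "BinnedTrack") -> bool:
        return self.bin_width == other.bin_width and {
            c: len(v) for c, v in self.signal.items()
        } == {c: len(v) for c, v in other.signal.items()}

    # ------------------------------------------------------------- I/O

    def write_bedgraph(self, path: str | Path) -> None:
        rows = []
        for chrom in sorted(self.signal):
            v = self.signal[chrom]
            for i, x in enumerate(v):
                rows.append(
                    (chrom, i * self.bin_width, (i + 1) * self.bin_width, x)
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bedgraph(
        cls, path: str | Path, bin_width: int, normalization: str = "raw"
    ) -> "BinnedTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
        signal: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            n = int(grp["end"].max()) // bin_width
            v = np.zeros(n)
            idx = (grp["start"].to_numpy() // bin_width).astype(int)
            v[idx] = grp["value"].to_numpy()
            signal[str(chrom)] = v
        return cls(bin_width=bin_width, signal=signal, normalization=normalization)


@dataclass
class GeneIntervals:
    """Per-gene genomic intervals with strand-aware TSS."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if np.any(self.table["start"] >= self.table["end"]):
            raise ValueError("intervals must satisfy start < end")
        self.table = self.table.reset_index(drop=True)

    def tss(self) -> np.ndarray:
        return np.where(
            self.table["strand"] == "+", self.table["start"], self.table["end"] - 1
        )

    @classmethod
    def read_bed(cls, path: str | Path) -> "GeneIntervals":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :6]
        df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"][
            : df.shape[1]
        ]
        if "strand" not in df.columns:
            df["strand"] = "+"
        if "gene_id" not in df.columns:
            df["gene_id"] = [f"region_{i}" for i in range(len(df))]
        return cls(df[["gene_id", "chrom", "start", "end", "strand"]])

    def write_bed(self, path: str | Path) -> None:
        out = self.table[["chrom", "start", "end", "gene_id"]].copy()
        out["score"] = 0
        out["strand"] = self.table["strand"]
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class TadSet:
    """Topologically associating domain intervals (0-based half-open)."""

    table: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        if np.any(self.table["start"] >= self.table["end"]):
            raise ValueError("TADs must satisfy start < end")
        if np.any(self.table["start"] < 0):
            raise ValueError("TAD coordinates must be non-negative")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def read_bed(cls, path: str | Path) -> "TadSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :3]
        df.columns = ["chrom", "start", "end"]
        return cls(df)

    def write_bed(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# track normalization and binarization
# --------------------------------------------------------------------------


def rpkm_bin_track(raw: BinnedTrack) -> BinnedTrack:
    """Reads-per-kilobase-per-million normalization of a raw binned track:
    value * 1e9 / (total_reads * bin_width)."""
    if raw.total_reads <= 0:
        raise ValueError("total_reads must be positive for RPKM normalization")
    scale = 1e9 / (raw.total_reads * raw.bin_width)
    return BinnedTrack(
        bin_width=raw.bin_width,
        signal={c: v * scale for c, v in raw.signal.items()},
        normalization="rpkm",
        total_reads=raw.total_reads,
    )


def binarize_track(
    track: BinnedTrack, p_threshold: float = 1e-4
) -> dict[str, np.ndarray]:
    """Poisson binarization of raw bin counts.

    A bin is called bound when its count is improbably high under a Poisson
    null whose rate is the genome-wide mean count per bin (upper-tail
    p < ``p_threshold``).
    """
    all_vals = np.concatenate([v for v in track.signal.values()]) if track.signal else np.array([])
    if all_vals.size == 0 or all_vals.sum() == 0:
        return {c: np.zeros(len(v), dtype=bool) for c, v in track.signal.items()}
    rate = all_vals.mean()
    out = {}
    for chrom, v in track.signal.items():
        # P(X >= k) under Poisson(rate)
        p_upper = stats.poisson.sf(np.rint(v) - 1, rate)
        out[chrom] = p_upper < p_threshold
    return out


# --------------------------------------------------------------------------
# gene-level quantification and differential calls
# --------------------------------------------------------------------------


def _interval_mean(track: BinnedTrack, chrom: str, start: int, end: int) -> float:
    """Overlap-weighted mean signal over [start, end)."""
    if chrom not in track.signal:
        raise ValueError(f"chromosome {chrom!r} absent from track")
    v = track.signal[chrom]
    length = len(v) * track.bin_width
    if start < 0 or end > length:
        warnings.warn(f"interval {chrom}:{start}-{end} clipped to chromosome bounds")
        start, end = max(start, 0), min(end, length)
    if start >= end:
        return 0.0
    b0 = start // track.bin_width
    b1 = (end - 1) // track.bin_width
    total = 0.0
    weight = 0.0
    for b in range(b0, b1 + 1):
        lo = max(start, b * track.bin_width)
        hi = min(end, (b + 1) * track.bin_width)
        total += v[b] * (hi - lo)
        weight += hi - lo
    return total / weight


def quantify_gene_marks(
    track: BinnedTrack,
    genes: GeneIntervals,
    promoter_up: int = 500,
    promoter_down: int = 500,
) -> pd.DataFrame:
    """Per-gene promoter and gene-body mean signal.

    The promoter window is TSS - promoter_up .. TSS + promoter_down in the
    direction of transcription (strand-aware); the body is the annotated
    gene interval.  Means are overlap-weighted over bins.
    """
    rows = []
    tss = genes.tss()
    for i, row in genes.table.iterrows():
        if row["strand"] == "+":
            p0, p1 = tss[i] - promoter_up, tss[i] + promoter_down
        else:
            p0, p1 = tss[i] - promoter_down, tss[i] + promoter_up
        rows.append(
            {
                "gene_id": row["gene_id"],
                "promoter_mean": _interval_mean(track, row["chrom"], int(p0), int(p1)),
                "body_mean": _interval_mean(
                    track, row["chrom"], int(row["start"]), int(row["end"])
                ),
            }
        )
    return pd.DataFrame(rows)


def differential_mark_call(
    wt: pd.DataFrame,
    kd: pd.DataFrame,
    lfc_threshold: float = 1.0,
    background: float | None = None,
    pseudocount: float = 1.0,
    on: str = "promoter_mean",
) -> pd.DataFrame:
    """Gain/loss calls of a mark between wild-type and knockdown.

    ``loss`` when log2((kd + pc)/(wt + pc)) <= -lfc_threshold with the WT
    level above background; ``gain`` for the mirror condition;
    ``below_background`` when both conditions sit under the background level;
    otherwise ``stable``.  Background defaults to the genome-wide median of
    the WT quantification.
    """
    if not wt["gene_id"].equals(kd["gene_id"]):
        raise ValueError("WT and KD tables must cover the same genes in order")
    w = wt[on].to_numpy(float)
    k = kd[on].to_numpy(float)
    if background is None:
        background = float(np.median(w))
    log2fc = np.log2((k + pseudocount) / (w + pseudocount))
    call = np.where(
        (w <= background) & (k <= background),
        "below_background",
        np.where(
            (log2fc <= -lfc_threshold) & (w > background),
            "loss",
            np.where((log2fc >= lfc_threshold) & (k > background), "gain", "stable"),
        ),
    )
    return pd.DataFrame(
        {
            "gene_id": wt["gene_id"],
            "wt": w,
            "kd": k,
            "log2fc": log2fc,
            "call": call,
        }
    )


def redistribution_summary(
    wt_bound: dict[str, np.ndarray], kd_bound: dict[str, np.ndarray]
) -> dict:
    """2x2 classification of bins by bound state in WT vs KD.

    The redistribution index min(lost, gained)/max(lost, gained) is 1 for a
    pure move of the mark to new loci and 0 for one-sided loss or gain.
    """
    if set(wt_bound) != set(kd_bound) or any(
        len(wt_bound[c]) != len(kd_bound[c]) for c in wt_bound
    ):
        raise ValueError("binning mismatch between WT and KD binarizations")
    n_lost = n_gained = n_sb = n_su = 0
    for c in wt_bound:
        w, k = wt_bound[c], kd_bound[c]
        n_lost += int(np.sum(w & ~k))
        n_gained += int(np.sum(~w & k))
        n_sb += int(np.sum(w & k))
        n_su += int(np.sum(~w & ~k))
    if n_lost == 0 or n_gained == 0:
        index = 0.0
    else:
        index = min(n_lost, n_gained) / max(n_lost, n_gained)
    return {
        "n_lost": n_lost,
        "n_gained": n_gained,
        "n_stable_bound": n_sb,
        "n_stable_unbound": n_su,
        "redistribution_index": index,
    }


# --------------------------------------------------------------------------
# meta-region matrices
# --------------------------------------------------------------------------


def _scaled_profile(
    track: BinnedTrack,
    chrom: str,
    start: int,
    end: int,
    flank: int,
    body_bins: int,
) -> np.ndarray:
    """Fixed-flank + scaled-body signal profile for one region."""
    bw = track.bin_width
    flank_bins = max(flank // bw, 1)
    if end - start < bw:
        warnings.warn(f"region {chrom}:{start}-{end} shorter than one bin")
    chrom_len = track.chrom_length(chrom)

    def flank_value(lo: int) -> float:
        hi = min(lo + bw, chrom_len)
        lo = max(lo, 0)
        return _interval_mean(track, chrom, lo, hi) if hi > lo else 0.0

    left = np.array([flank_value(start - flank + i * bw) for i in range(flank_bins)])
    right = np.array([flank_value(end + i * bw) for i in range(flank_bins)])
    # body: sample the raw per-bin signal and rescale to body_bins columns
    b0 = start // bw
    b1 = max((end - 1) // bw, b0)
    body_raw = track.signal[chrom][b0 : b1 + 1]
    xp = np.linspace(0.0, 1.0, len(body_raw))
    xq = np.linspace(0.0, 1.0, body_bins)
    body = np.interp(xq, xp, body_raw) if len(body_raw) > 1 else np.full(
        body_bins, body_raw[0] if len(body_raw) else 0.0
    )
    return np.concatenate([left, body, right])


def tad_metaregion_matrix(
    values: pd.DataFrame,
    regions: "TadSet | GeneIntervals",
    track: BinnedTrack,
    genes: GeneIntervals | None = None,
    flank: int = 3000,
    body_bins: int = 100,
    lfc_threshold: float = 1.0,
) -> dict:
    """Scaled meta-region matrix over TADs (or genes) plus DE placement.

    ``values`` is a per-gene table with columns gene_id and log2fc (the DE
    stage output).  Rows of the matrix are regions; columns are ``flank``
    fixed-width bins either side of a body rescaled to ``body_bins`` columns.
    Rows are sorted by log2FC within cluster (upregulated / nontarget /
    downregulated, by the log2FC sign at ``lfc_threshold``).  When both TADs
    and gene intervals are supplied, the fraction of DE genes whose midpoint
    lies inside a TAD is reported.
    """
    region_table = regions.table
    is_gene_regions = "gene_id" in region_table.columns

    vals = values.set_index("gene_id")["log2fc"]

    rows = []
    meta = []
    for i, row in region_table.iterrows():
        profile = _scaled_profile(
            track, row["chrom"], int(row["start"]), int(row["end"]), flank, body_bins
        )
        if is_gene_regions:
            lfc = float(vals.get(row["gene_id"], 0.0))
            label = row["gene_id"]
        else:
            inside = _genes_in_interval(genes, row) if genes is not None else []
            lfc = (
                float(np.nanmean([vals.get(g, np.nan) for g in inside]))
                if inside
                else 0.0
            )
            if np.isnan(lfc):
                lfc = 0.0
            label = f"{row['chrom']}:{row['start']}-{row['end']}"
        cluster = (
            "upregulated"
            if lfc >= lfc_threshold
            else "downregulated" if lfc <= -lfc_threshold else "nontarget"
        )
        rows.append(profile)
        meta.append({"region": label, "log2fc": lfc, "cluster": cluster})

    matrix = np.vstack(rows) if rows else np.empty((0, 0))
    meta_df = pd.DataFrame(meta)
    order = []
    for cluster in ("upregulated", "nontarget", "downregulated"):
        sub = meta_df[meta_df["cluster"] == cluster]
        order.extend(sub.sort_values("log2fc", ascending=False).index.tolist())
    matrix = matrix[order] if len(order) else matrix
    meta_df = meta_df.loc[order].reset_index(drop=True)

    out = {
        "matrix": matrix,
        "rows": meta_df,
        "n_columns": matrix.shape[1] if matrix.size else 0,
        "flank_bins": max(flank // track.bin_width, 1),
        "body_bins": body_bins,
    }
    if genes is not None and not is_gene_regions:
        out["within_tad_fraction"] = within_tad_fraction(
            genes, regions, de_genes=set(values["gene_id"])
        )
    return out


def _genes_in_interval(genes: GeneIntervals, region: pd.Series) -> list[str]:
    t = genes.table
    mid = (t["start"] + t["end"]) // 2
    sel = (
        (t["chrom"] == region["chrom"])
        & (mid >= region["start"])
        & (mid < region["end"])
    )
    return t.loc[sel, "gene_id"].tolist()


def within_tad_fraction(
    genes: GeneIntervals, tads: TadSet, de_genes: set[str] | None = None
) -> float:
    """Fraction of (DE) genes whose midpoint lies inside some TAD."""
    t = genes.table
    if de_genes is not None:
        t = t[t["gene_id"].isin(de_genes)]
    if t.empty:
        return 0.0
    inside = 0
    for _, row in t.iterrows():
        mid = (row["start"] + row["end"]) // 2
        hit = tads.table[
            (tads.table["chrom"] == row["chrom"])
            & (tads.table["start"] <= mid)
            & (mid < tads.table["end"])
        ]
        if len(hit):
            inside += 1
    return inside / len(t)
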