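"""Gene-by-sample count matrix with per-sample metadata.

The :class:`CountMatrix` is the substrate shared by the differential-expression,
translational-efficiency and signature stages.  Counts are raw (unnormalized)
non-negative integers; per-sample metadata records genotype, RNA fraction
(``input`` / ``polysome`` / ``none``), developmental stage and replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FRACTIONS = ("input", "polysome", "none")


@dataclass
class SampleInfo:
    """Metadata for one sequencing library."""

    sample_id: str
    genotype: str
    fraction: str = "none"
    stage: str = "none"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )


@dataclass
class CountMatrix:
    """Raw gene x sample counts plus sample metadata.

    Invariants (checked on construction): dimensions match the id lists, counts
    are non-negative integers, ids are unique, and every sample has metadata.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)
    metadata: dict[str, SampleInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts != np.floor(self.counts)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not self.metadata:
            self.metadata = {
                s: SampleInfo(sample_id=s, genotype="unknown") for s in self.sample_ids
            }
        missing = [s for s in self.sample_ids if s not in self.metadata]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return CountMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts[rows, :],
            metadata=dict(self.metadata),
        )

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, cols],
            metadata={s: self.metadata[s] for s in sample_ids},
        )

    def samples_with(self, **criteria: str) -> list[str]:
        """Sample ids whose metadata match all given field=value criteria."""
        out = []
        for s in self.sample_ids:
            info = self.metadata[s]
            if all(getattr(info, k) == v for k, v in criteria.items()):
                out.append(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    # ---------------------------------------------------------------- I/O

    def write_tsv(self, counts_path: str | Path, meta_path: str | Path | None = None) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(counts_path, sep="\t")
        if meta_path is not None:
            meta = pd.DataFrame(
                [
                    {
                        "sample_id": s,
                        "genotype": self.metadata[s].genotype,
                        "fraction": self.metadata[s].fraction,
                        "stage": self.metadata[s].stage,
                        "replicate": self.metadata[s].replicate,
                    }
                    for s in self.sample_ids
                ]
            )
            meta.to_csv(meta_path, sep="\t", index=False)


def read_counts_tsv(counts_path: str | Path, meta_path: str | Path | None = None) -> CountMatrix:
    """Read a count table (first column gene id, header row of sample ids) and
    optional sample-metadata TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    metadata: dict[str, SampleInfo] = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
        for _, row in meta.iterrows():
            metadata[str(row["sample_id"])] = SampleInfo(
                sample_id=str(row["sample_id"]),
                genotype=str(row.get("genotype", "unknown")),
                fraction=str(row.get("fraction", "none")),
                stage=str(row.get("stage", "none")),
                replicate=int(row.get("replicate", 1)),
            )
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(),
        metadata=metadata,
    )
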