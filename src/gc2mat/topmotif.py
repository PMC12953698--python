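"""TOP-motif classification from CAGE transcription start sites.

CAGE-seq reads mark capped 5' ends, so the modal CAGE position within a
window around a transcript's annotated start is taken as its dominant TSS.
A transcript carries a 5' terminal oligopyrimidine (TOP) motif when the
sequence read from that TSS starts with a C or U and continues in an
uninterrupted pyrimidine run of at least ``min_run`` bases (the first base
included).  TOP mRNAs are the classic TORC1-sensitive translation targets,
which is why the motif matters for ribosome-level regulators.

Coordinates are 0-based half-open (bedGraph convention); minus-strand
profiles are read 3'->5' in genome coordinates, so the 5'-most position is
the largest coordinate there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

PYRIMIDINES = frozenset("CTU")
VALID_BASES = frozenset("ACGTU")


@dataclass
class CageProfile:
    """Per-position CAGE 5'-end counts for one transcript."""

    transcript_id: str
    strand: str
    counts: dict[int, int]  # genomic position -> 5'-end read count

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("CAGE counts must be non-negative")


@dataclass
class TopCall:
    """TOP classification of one transcript."""

    transcript_id: str
    tss_position: int | None
    five_prime_sequence: str
    first_base: str
    pyrimidine_run_length: int
    is_top: bool


def call_tss_from_cage(profile: CageProfile) -> int:
    """Dominant TSS = position of the maximum CAGE count.

    Ties are broken toward the 5'-most position (smallest coordinate on the
    plus strand, largest on the minus strand), which favors the longest
    5' UTR and is therefore conservative for TOP detection.
    """
    positive = {p: c for p, c in profile.counts.items() if c > 0}
    if not positive:
        raise ValueError(
            f"all-zero CAGE profile for transcript {profile.transcript_id!r}"
        )
    best = max(positive.values())
    candidates = [p for p, c in positive.items() if c == best]
    return min(candidates) if profile.strand == "+" else max(candidates)


def classify_top_motif(
    five_prime_sequence: str,
    min_run: int = 5,
    transcript_id: str = "",
    tss_position: int | None = None,
) -> TopCall:
    """Classify a 5'->3' transcript-leader sequence as TOP or non-TOP.

    TOP requires the first base to be a pyrimidine (C or U/T in DNA space)
    and the initial pyrimidine run, counting that first base, to reach
    ``min_run``.  Case-insensitive; T and U are equivalent.
    """
    if not five_prime_sequence:
        raise ValueError("empty 5' sequence")
    seq = five_prime_sequence.upper()
    for i, base in enumerate(seq):
        if base not in VALID_BASES:
            raise ValueError(f"invalid character {base!r} at position {i}")
    run = 0
    for base in seq:
        if base in PYRIMIDINES:
            run += 1
        else:
            break
    first = seq[0]
    return TopCall(
        transcript_id=transcript_id,
        tss_position=tss_position,
        five_prime_sequence=five_prime_sequence,
        first_base=first,
        pyrimidine_run_length=run,
        is_top=(first in PYRIMIDINES) and run >= min_run,
    )


def call_top_from_cage(
    profile: CageProfile,
    genome_seq: str,
    min_run: int = 5,
    leader_length: int = 30,
) -> TopCall:
    """Full pipeline for one transcript: modal TSS, then motif classification.

    ``genome_seq`` is the plus-strand chromosome sequence; for minus-strand
    transcripts the leader is reverse-complemented so it reads 5'->3'.
    """
    tss = call_tss_from_cage(profile)
    if profile.strand == "+":
        leader = genome_seq[tss : tss + leader_length]
    else:
        leader = _revcomp(genome_seq[max(tss + 1 - leader_length, 0) : tss + 1])
    call = classify_top_motif(
        leader, min_run=min_run, transcript_id=profile.transcript_id,
        tss_position=tss,
    )
    return call


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --------------------------------------------------------------------------
# I/O: strand-split bedGraph of 5'-end counts + BED of transcript windows
# --------------------------------------------------------------------------


def read_cage_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, count), 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "count"],
    )
    return df


def profiles_from_bedgraph(
    plus: pd.DataFrame,
    minus: pd.DataFrame,
    transcripts: pd.DataFrame,
    window: int = 50,
) -> list[CageProfile]:
    """Build per-transcript CAGE profiles around annotated starts.

    ``transcripts`` needs columns chrom, start, end, name, strand (BED6-like);
    the annotated start is ``start`` on +, ``end - 1`` on -.  Positions within
    ``window`` bp of the annotated start contribute.
    """
    profiles = []
    for _, tx in transcripts.iterrows():
        strand = tx["strand"]
        anchor = int(tx["start"]) if strand == "+" else int(tx["end"]) - 1
        source = plus if strand == "+" else minus
        sel = source[
            (source["chrom"] == tx["chrom"])
            & (source["start"] >= anchor - window)
            & (source["start"] <= anchor + window)
        ]
        counts: dict[int, int] = {}
        for _, row in sel.iterrows():
            for pos in range(int(row["start"]), int(row["end"])):
                if anchor - window <= pos <= anchor + window:
                    counts[pos] = counts.get(pos, 0) + int(row["count"])
        profiles.append(
            CageProfile(transcript_id=str(tx["name"]), strand=strand, counts=counts)
        )
    return profiles
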