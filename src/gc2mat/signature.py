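"""Stage-signature regression and profile classification.

Signature cohorts (e.g. the shared upregulated targets of several germline
knockdowns) are profiled across libraries enriched for different germline
stages — germline stem cells (GSC), cystoblasts (CB), cysts and whole
ovaries — or across genotypes.  A negative-binomial regression with the
group label as the sole predictor estimates the average TPM of the signature
genes per group; contrasts between groups give Wald p-values, adjusted by
Benjamini-Hochberg across the contrast family.

TPM is continuous while the NB likelihood is for counts, so values are
rounded to the nearest integer before fitting; this is recorded in the
result.  Genes are the observational units (one observation per gene per
library); no per-gene random effects are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genesets import GeneSet
from .nbglm import bh_adjust

STAGES = ("GSC", "CB", "cyst", "whole_ovary")


@dataclass
class StageExpressionTable:
    """Gene x library TPM table with a group label per library."""

    gene_ids: list[str]
    library_ids: list[str]
    groups: list[str]  # per-library group label (stage or genotype)
    tpm: np.ndarray  # (n_genes, n_libraries), non-negative

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.gene_ids), len(self.library_ids)):
            raise ValueError("tpm shape does not match id lists")
        if len(self.groups) != len(self.library_ids):
            raise ValueError("one group label per library required")
        if np.any(self.tpm < 0):
            raise ValueError("TPM must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tpm, index=self.gene_ids, columns=self.library_ids)


def read_tpm_tsv(path, groups: dict[str, str] | None = None) -> StageExpressionTable:
    """Read a gene x library TPM TSV; by default each library's group label is
    its own column name."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    libs = [str(c) for c in df.columns]
    grp = [groups.get(c, c) if groups else c for c in libs]
    return StageExpressionTable(
        gene_ids=[str(g) for g in df.index],
        library_ids=libs,
        groups=grp,
        tpm=df.to_numpy(),
    )


def _nb_alpha_moment(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion given fitted means."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    if den <= 0:
        return 0.0
    return float(max(num / den, 0.0))


def fit_stage_nb_regression(
    table: StageExpressionTable,
    signature: GeneSet,
    contrasts: list[tuple[str, str]],
) -> pd.DataFrame:
    """NB regression of signature-gene TPM on the group label.

    Each (gene, library) pair contributes one observation; rounded TPM is the
    response and the group the sole predictor (cell-means coding).  For each
    requested contrast ``(a, b)`` the log mean ratio a/b, its Wald p and the
    BH-adjusted p across the contrast family are reported.
    """
    members = [g for g in table.gene_ids if g in signature.members]
    if not members:
        raise ValueError("signature has no genes in the table")
    idx = [table.gene_ids.index(g) for g in members]
    groups = sorted(set(table.groups))
    for a, b in contrasts:
        for lab in (a, b):
            if lab not in groups:
                raise ValueError(f"contrast references absent group {lab!r}")

    y = np.rint(table.tpm[idx, :]).ravel()
    obs_groups = np.tile(np.array(table.groups), len(members))
    X = np.zeros((y.size, len(groups)))
    for j, g in enumerate(groups):
        X[:, j] = (obs_groups == g).astype(float)

    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    alpha = _nb_alpha_moment(y, pois.fittedvalues)
    if alpha > 0:
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    else:
        fit = pois

    rows = []
    for a, b in contrasts:
        c = np.zeros(len(groups))
        c[groups.index(a)] = 1.0
        c[groups.index(b)] = -1.0
        t = fit.t_test(c)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "log_ratio": float(np.squeeze(t.effect)),
                "se": float(np.squeeze(t.sd)),
                "pvalue": float(np.squeeze(t.pvalue)),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out.attrs["nb_alpha"] = alpha
    out.attrs["n_signature_genes"] = len(members)
    out.attrs["response"] = "TPM rounded to nearest integer"
    return out


def classify_stage_profile(
    table: StageExpressionTable, gene: str, ratio: float = 2.0
) -> str:
    """Classify one gene's stage profile.

    ``germ_cell_like`` when the mean of the undifferentiated stages
    (GSC, CB, cyst) is at least ``ratio`` times the whole-ovary level;
    ``maternal_like`` for the reverse; ``flat`` when neither and the profile
    is within the ratio band; ``other`` for zero-expression edge cases.
    """
    missing = [s for s in STAGES if s not in table.groups]
    if missing:
        raise ValueError(f"missing stages: {missing}")
    i = table.gene_ids.index(gene)
    by_stage = {
        s: float(
            np.mean([table.tpm[i, j] for j, g in enumerate(table.groups) if g == s])
        )
        for s in STAGES
    }
    early = np.mean([by_stage["GSC"], by_stage["CB"], by_stage["cyst"]])
    ovary = by_stage["whole_ovary"]
    if early == 0 and ovary == 0:
        return "other"
    if early >= ratio * ovary:
        return "germ_cell_like"
    if ovary >= ratio * early:
        return "maternal_like"
    return "flat"


def classify_stage_profiles(
    table: StageExpressionTable, ratio: float = 2.0
) -> pd.DataFrame:
    """Vectorized profile classification for every gene in the table."""
    return pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "profile": [
                classify_stage_profile(table, g, ratio) for g in table.gene_ids
            ],
        }
    )
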