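import numpy as np
import pytest

from gc2mat.countmatrix import CountMatrix, SampleInfo


def make_counts(counts, genotypes=None, fractions=None, gene_ids=None):
    """Build a CountMatrix from a plain array with minimal metadata."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i:04d}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    genotypes = genotypes or ["wt"] * n_samples
    fractions = fractions or ["none"] * n_samples
    metadata = {
        s: SampleInfo(sample_id=s, genotype=g, fraction=f)
        for s, g, f in zip(sample_ids, genotypes, fractions)
    }
    return CountMatrix(gene_ids, sample_ids, counts, metadata)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_counts(rng):
    """NB counts, 300 genes, two groups of 4, no true differences."""
    mu = np.exp(rng.normal(np.log(200), 1.0, 300))
    lam = rng.gamma(1 / 0.1, 0.1 * mu[:, None], (300, 8))
    y = rng.poisson(lam)
    return make_counts(y, genotypes=["a"] * 4 + ["b"] * 4)
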