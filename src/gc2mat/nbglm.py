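"""Negative-binomial count-model engine.

Shared by the differential-expression, translational-efficiency and
stage-signature stages.  Implements:

* library-composition normalization — median-of-ratios size factors and
  trimmed-mean-of-M-values (TMM) factors;
* per-gene dispersion estimation by Cox–Reid adjusted profile likelihood with
  empirical-Bayes shrinkage toward a common dispersion;
* per-gene NB generalized linear models with log link and offsets, fitted by
  iteratively reweighted least squares (vectorized across genes);
* Wald tests and likelihood-ratio tests of arbitrary coefficient contrasts;
* Benjamini–Hochberg step-up adjustment.

The NB parameterization is mean/dispersion: ``Var(Y) = mu + alpha * mu**2``,
so ``alpha = 0`` is the Poisson limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .countmatrix import CountMatrix

_ETA_LO, _ETA_HI = -30.0, 30.0
_POISSON_ALPHA = 1e-8  # dispersions at/below this are treated as Poisson


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------


@dataclass
class Design:
    """A sample x coefficient design matrix with named coefficients."""

    matrix: np.ndarray
    coef_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.coef_names):
            raise ValueError("design matrix shape does not match coefficient names")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is not full rank")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]


def one_hot_design(labels: list[str], level_order: list[str] | None = None) -> Design:
    """Cell-means (one-hot) design: one indicator column per group level."""
    levels = level_order if level_order is not None else sorted(set(labels))
    missing = set(labels) - set(levels)
    if missing:
        raise ValueError(f"labels not in level order: {sorted(missing)}")
    mat = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        mat[i, levels.index(lab)] = 1.0
    return Design(matrix=mat, coef_names=list(levels))


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


@dataclass
class NormalizationFactors:
    """Per-sample normalization factors.

    For ``method="median_ratios"`` the factors are DESeq2-style size factors
    (they absorb sequencing depth); for ``method="tmm"`` they are
    composition-correction factors multiplying the library size, with
    geometric mean 1.
    """

    factors: np.ndarray
    method: str
    reference_sample: str

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("normalization factors must be positive")

    def offsets(self, library_sizes: np.ndarray | None = None) -> np.ndarray:
        """Per-sample log offset for the NB GLM."""
        if self.method == "median_ratios":
            return np.log(self.factors)
        if library_sizes is None:
            raise ValueError("TMM offsets require library sizes")
        return np.log(np.asarray(library_sizes, float) * self.factors)


def estimate_size_factors(counts: CountMatrix) -> NormalizationFactors:
    """Median-of-ratios size factors.

    For each sample the factor is the median, over genes expressed in every
    sample, of the ratio of that gene's count to its across-sample geometric
    mean.
    """
    y = counts.counts.astype(float)
    allpos = np.all(y > 0, axis=1)
    if not np.any(allpos):
        raise ValueError(
            "median-of-ratios requires at least one gene with positive counts "
            "in every sample"
        )
    yp = y[allpos, :]
    geomean = np.exp(np.log(yp).mean(axis=1, keepdims=True))
    factors = np.median(yp / geomean, axis=0)
    return NormalizationFactors(
        factors=factors, method="median_ratios", reference_sample="geometric_mean"
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale inputs)."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic inverse precision of M (binomial delta method)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def estimate_tmm_factors(
    counts: CountMatrix,
    ref: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values composition factors.

    M-values (log2 relative abundance ratios against a reference sample) are
    trimmed by ``logratio_trim`` in each tail, A-values by ``sum_trim`` in each
    tail, and the remaining M-values are averaged with inverse-variance
    precision weights.  Factors are centered to geometric mean 1.  When no
    reference is given, the sample whose upper-quartile relative abundance is
    closest to the mean upper-quartile is used.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM requires at least two samples")
    y = counts.counts.astype(float)
    libsize = y.sum(axis=0)
    if np.any(libsize == 0):
        bad = [s for s, n in zip(counts.sample_ids, libsize) if n == 0]
        raise ValueError(f"samples with all-zero counts: {bad}")
    if ref is None:
        f75 = np.array(
            [np.quantile(y[:, j] / libsize[j], 0.75) for j in range(counts.n_samples)]
        )
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.sample_ids.index(ref)
    factors = np.array(
        [
            _tmm_pair(
                y[:, j], y[:, ref_idx], libsize[j], libsize[ref_idx],
                logratio_trim, sum_trim,
            )
            for j in range(counts.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=factors, method="tmm", reference_sample=counts.sample_ids[ref_idx]
    )


# --------------------------------------------------------------------------
# NB likelihood and batched IRLS
# --------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray | float) -> np.ndarray:
    """Row-wise NB(2) log-likelihood; Poisson limit for tiny dispersion.

    ``y`` and ``mu`` have shape (G, n); ``alpha`` is scalar or (G,).  Returns
    shape (G,).
    """
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-300)
    alpha = np.broadcast_to(np.asarray(alpha, float), (y.shape[0],))
    out = np.empty(y.shape[0])
    pois = alpha <= _POISSON_ALPHA
    if np.any(pois):
        yp, mp = y[pois], mu[pois]
        out[pois] = np.sum(yp * np.log(mp) - mp - gammaln(yp + 1.0), axis=1)
    if np.any(~pois):
        yn, mn = y[~pois], mu[~pois]
        size = 1.0 / alpha[~pois, None]  # NB "size" r
        out[~pois] = np.sum(
            gammaln(yn + size)
            - gammaln(size)
            - gammaln(yn + 1.0)
            + yn * np.log(mn / (mn + size))
            + size * np.log(size / (mn + size)),
            axis=1,
        )
    return out


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray | float) -> np.ndarray:
    """Row-wise NB deviance (2 * (saturated ll - model ll))."""
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-300)
    alpha = np.broadcast_to(np.asarray(alpha, float), (y.shape[0],))[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    pois = alpha <= _POISSON_ALPHA
    nb_part = np.where(
        pois,
        y - mu,
        (y + 1.0 / np.maximum(alpha, 1e-300))
        * np.log((1.0 + alpha * y) / (1.0 + alpha * mu)),
    )
    return 2.0 * np.sum(ylogy - nb_part, axis=1)


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    alpha: np.ndarray | float,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized-across-genes IRLS for the NB GLM with log link.

    Returns (beta (G,p), mu (G,n), deviance (G,), converged (G,)).
    """
    y = np.asarray(y, float)
    G, n = y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, float), (G,))
    offsets = np.broadcast_to(np.asarray(offsets, float), (n,))

    if beta0 is None:
        mu = y + np.maximum(y.mean(axis=1, keepdims=True), 1.0) / 6.0
        eta = np.clip(np.log(mu), _ETA_LO, _ETA_HI)
        z = eta - offsets
        w = mu / (1.0 + alpha[:, None] * mu)
        beta = _solve_wls(X, w, z)
    else:
        beta = beta0.copy()

    eta = np.clip(beta @ X.T + offsets, _ETA_LO, _ETA_HI)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, alpha)
    converged = np.zeros(G, dtype=bool)

    for _ in range(max_iter):
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offsets) + (y - mu) / np.maximum(mu, 1e-300)
        beta_new = _solve_wls(X, w, z)
        eta_new = np.clip(beta_new @ X.T + offsets, _ETA_LO, _ETA_HI)
        mu_new = np.exp(eta_new)
        dev_new = nb_deviance(y, mu_new, alpha)
        # step-halve genes whose deviance increased
        worse = dev_new > dev + 1e-10
        halvings = 0
        while np.any(worse) and halvings < 10:
            beta_new[worse] = 0.5 * (beta_new[worse] + beta[worse])
            eta_new[worse] = np.clip(
                beta_new[worse] @ X.T + offsets, _ETA_LO, _ETA_HI
            )
            mu_new[worse] = np.exp(eta_new[worse])
            dev_new[worse] = nb_deviance(y[worse], mu_new[worse], alpha[worse])
            worse = dev_new > dev + 1e-10
            halvings += 1
        delta = np.abs(dev_new - dev) / (np.abs(dev_new) + 0.1)
        newly = delta < tol
        beta, eta, mu, dev = beta_new, eta_new, mu_new, dev_new
        converged = converged | newly
        if np.all(converged):
            break
    return beta, mu, dev, converged


def _solve_wls(X: np.ndarray, w: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Batched weighted least squares: per gene solve (X'WX) b = X'Wz."""
    A = np.einsum("ni,gn,nj->gij", X, w, X)
    b = np.einsum("ni,gn,gn->gi", X, w, z)
    p = X.shape[1]
    A = A + 1e-10 * np.eye(p)[None, :, :]
    return np.linalg.solve(A, b[..., None])[..., 0]


def _fisher_info(X: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Batched Fisher information X'WX with NB working weights."""
    w = mu / (1.0 + alpha[:, None] * mu)
    return np.einsum("ni,gn,nj->gij", X, w, X)


# --------------------------------------------------------------------------
# dispersion estimation
# --------------------------------------------------------------------------


@dataclass
class DispersionEstimates:
    """Gene-wise, common and shrunk NB dispersions."""

    genewise: np.ndarray
    common: float
    shrunk: np.ndarray
    prior_df: float

    def __post_init__(self) -> None:
        if np.any(self.genewise < 0) or np.any(self.shrunk < 0) or self.common < 0:
            raise ValueError("dispersions must be non-negative")


def _apl_grid(
    y: np.ndarray, X: np.ndarray, offsets: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood at each grid dispersion.

    Returns shape (n_grid, G).  The CR adjustment subtracts half the
    log-determinant of the Fisher information, which removes most of the bias
    from estimating the mean parameters.
    """
    G = y.shape[0]
    apls = np.empty((grid.size, G))
    beta = None
    for k, a in enumerate(grid):
        beta, mu, _, _ = _irls_nb(y, X, offsets, a, beta0=beta)
        info = _fisher_info(X, mu, np.full(G, a))
        sign, logdet = np.linalg.slogdet(info + 1e-10 * np.eye(X.shape[1]))
        apls[k] = nb_loglik(y, mu, a) - 0.5 * logdet
    return apls


def _argmax_refined(grid_log: np.ndarray, vals: np.ndarray) -> float:
    """Parabolic refinement of the grid argmax on the log-dispersion axis."""
    k = int(np.argmax(vals))
    if k == 0 or k == vals.size - 1:
        return float(np.exp(grid_log[k]))
    x0, x1, x2 = grid_log[k - 1], grid_log[k], grid_log[k + 1]
    y0, y1, y2 = vals[k - 1], vals[k], vals[k + 1]
    denom = (y0 - 2 * y1 + y2)
    if abs(denom) < 1e-12:
        return float(np.exp(x1))
    x = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) / (
        (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    )
    x = float(np.clip(x, x0, x2))
    return float(np.exp(x))


def estimate_dispersions(
    counts: CountMatrix,
    design: Design,
    norm: NormalizationFactors,
    prior_df: float = 10.0,
    grid_min: float = 1e-6,
    grid_max: float = 10.0,
    grid_points: int = 25,
) -> DispersionEstimates:
    """Estimate NB dispersions by CR adjusted profile likelihood on a log grid.

    Gene-wise maxima are shrunk toward the common (all-gene) maximum with
    weight ``prior_df / (prior_df + residual_df)`` on the log scale; the
    shrunk value always lies between the gene-wise and common estimates.
    """
    if design.n_samples - design.n_coef < 1:
        raise ValueError("no residual degrees of freedom for dispersion estimation")
    y = counts.counts.astype(float)
    nonzero = y.sum(axis=1) > 0
    offsets = norm.offsets(counts.library_sizes())
    grid = np.exp(np.linspace(np.log(grid_min), np.log(grid_max), grid_points))
    apls = _apl_grid(y[nonzero], design.matrix, offsets, grid)
    log_grid = np.log(grid)

    genewise_nz = np.array(
        [_argmax_refined(log_grid, apls[:, g]) for g in range(apls.shape[1])]
    )
    common = _argmax_refined(log_grid, apls.sum(axis=1))

    genewise = np.full(counts.n_genes, common)
    genewise[nonzero] = genewise_nz

    resid_df = design.n_samples - design.n_coef
    w = prior_df / (prior_df + resid_df)
    shrunk = np.exp(
        w * np.log(np.maximum(common, grid_min))
        + (1 - w) * np.log(np.maximum(genewise, grid_min))
    )
    return DispersionEstimates(
        genewise=genewise, common=float(common), shrunk=shrunk, prior_df=prior_df
    )


# --------------------------------------------------------------------------
# GLM fitting and tests
# --------------------------------------------------------------------------


@dataclass
class GlmFit:
    """Per-gene NB GLM fit (natural-log coefficients)."""

    gene_ids: list[str]
    design: Design
    coefficients: np.ndarray  # (G, p)
    mu: np.ndarray  # (G, n) fitted means
    deviance: np.ndarray  # (G,)
    loglik: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    degenerate: np.ndarray  # (G,) bool: all-zero genes
    offsets: np.ndarray  # (n,)
    dispersions: np.ndarray  # (G,)
    counts: np.ndarray  # (G, n) raw counts


def fit_nb_glm(
    counts: CountMatrix,
    design: Design,
    norm: NormalizationFactors,
    disp: DispersionEstimates | np.ndarray | float,
) -> GlmFit:
    """Fit one NB GLM per gene with log link and normalization offsets."""
    if design.n_samples != counts.n_samples:
        raise ValueError("design rows do not match sample count")
    y = counts.counts.astype(float)
    offsets = norm.offsets(counts.library_sizes())
    if isinstance(disp, DispersionEstimates):
        alpha = disp.shrunk
    else:
        alpha = np.broadcast_to(np.asarray(disp, float), (counts.n_genes,))
    beta, mu, dev, conv = _irls_nb(y, design.matrix, offsets, alpha)
    degenerate = y.sum(axis=1) == 0
    conv = conv | degenerate  # all-zero genes sit at the boundary, fit is final
    return GlmFit(
        gene_ids=list(counts.gene_ids),
        design=design,
        coefficients=beta,
        mu=mu,
        deviance=dev,
        loglik=nb_loglik(y, mu, alpha),
        converged=conv,
        degenerate=degenerate,
        offsets=offsets,
        dispersions=np.asarray(alpha, float).copy(),
        counts=counts.counts.copy(),
    )


def wald_test(fit: GlmFit, contrast: np.ndarray) -> pd.DataFrame:
    """Wald test of a coefficient contrast.

    The statistic is estimate / SE with SE from the inverse Fisher
    information; p-values are two-sided normal.  Genes with zero SE (e.g.
    all-zero genes) get NaN p-values and class ``filtered``.
    """
    contrast = np.asarray(contrast, float)
    if contrast.size != fit.design.n_coef:
        raise ValueError("contrast length does not match coefficient count")
    est = fit.coefficients @ contrast
    info = _fisher_info(fit.design.matrix, fit.mu, fit.dispersions)
    cov = np.linalg.inv(info + 1e-10 * np.eye(fit.design.n_coef)[None])
    var = np.einsum("i,gij,j->g", contrast, cov, contrast)
    se = np.sqrt(np.maximum(var, 0.0))
    ok = (se > 1e-12) & ~fit.degenerate
    stat = np.where(ok, est / np.where(se > 1e-12, se, 1.0), np.nan)
    if np.all(contrast == 0):
        stat = np.zeros_like(est)
        pvals = np.ones_like(est)
        est = np.zeros_like(est)
    else:
        pvals = np.where(ok, 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "log2fc": est / np.log(2.0),
            "stat": stat,
            "pvalue": pvals,
            "fdr": fdr,
            "class": np.where(np.isnan(pvals), "filtered", "ns"),
        }
    )


def _contrast_basis(contrast: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q with first column parallel to the contrast.

    Reparameterizing the design as ``X @ Q`` makes the (scaled) contrast the
    first coefficient, so the LRT reduced model is simply the design without
    that column.
    """
    contrast = np.asarray(contrast, float)
    if np.all(contrast == 0):
        raise ValueError("contrast must be a nonzero vector")
    p = contrast.size
    A = np.eye(p)
    A[:, 0] = contrast
    q, _ = np.linalg.qr(A)
    # QR may flip the sign of the first column; align it with the contrast
    if np.dot(q[:, 0], contrast) < 0:
        q[:, 0] = -q[:, 0]
    if np.linalg.matrix_rank(q) < p:
        raise ValueError("could not complete contrast to a basis")
    return q


def lrt_contrast_test(
    counts: CountMatrix,
    design: Design,
    norm: NormalizationFactors,
    disp: DispersionEstimates | np.ndarray | float,
    contrast: np.ndarray,
) -> pd.DataFrame:
    """Likelihood-ratio test of a single contrast (1 df chi-square).

    The design is rotated so the contrast becomes one coefficient; the
    reduced model drops that coefficient and the statistic is twice the
    log-likelihood difference.  The reported ``log2fc`` is the contrast
    estimate from the full fit.
    """
    contrast = np.asarray(contrast, float)
    Q = _contrast_basis(contrast)
    full_design = Design(
        matrix=design.matrix @ Q,
        coef_names=[f"rot{k}" for k in range(design.n_coef)],
    )
    reduced_matrix = design.matrix @ Q[:, 1:]
    if np.linalg.matrix_rank(reduced_matrix) < design.n_coef - 1:
        raise ValueError("reduced design is rank deficient")
    reduced_design = Design(
        matrix=reduced_matrix,
        coef_names=[f"rot{k}" for k in range(1, design.n_coef)],
    )
    full = fit_nb_glm(counts, full_design, norm, disp)
    reduced = fit_nb_glm(counts, reduced_design, norm, disp)
    stat = np.maximum(2.0 * (full.loglik - reduced.loglik), 0.0)
    ok = ~full.degenerate
    pvals = np.where(ok, stats.chi2.sf(stat, df=1), np.nan)
    # contrast estimate on the original coefficients: c.beta = ||c|| * gamma_1
    est = full.coefficients[:, 0] * np.linalg.norm(contrast)
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "gene_id": list(counts.gene_ids),
            "log2fc": est / np.log(2.0),
            "stat": stat,
            "pvalue": pvals,
            "fdr": fdr,
            "class": np.where(np.isnan(pvals), "filtered", "ns"),
        }
    )


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries (filtered genes) are excluded from the number of tests and
    propagated as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    q = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out
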