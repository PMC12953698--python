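# Methods

This note records the statistical models, the defaults and why they were
chosen, the numerical choices, and what the synthetic-data harness does and
does not establish about real data.

## Negative-binomial count engine

All count-based stages share one engine (`gc2mat.nbglm`). Counts are NB with
the mean/dispersion parameterization Var(Y) = μ + αμ², log link, and a
per-library offset carrying normalization; α = 0 degenerates to Poisson and
is handled by a dedicated likelihood branch below α = 1e-8.

**Normalization.** Two estimators are provided. Median-of-ratios size
factors: for each library, the median over genes expressed in every library
of the count divided by the gene's across-library geometric mean (the median
is taken on the ratio scale, not the log scale, which matters only for
even-count interpolation). TMM: M- and A-values against a reference library
(the one whose upper-quartile relative abundance is closest to the mean
upper-quartile), 30% trim on each M tail and 5% on each A tail, then an
inverse-variance weighted mean of surviving M-values using the binomial
delta-method precision weights; factors are centered to geometric mean 1.
These trims and the reference rule are the established TMM defaults; the
implementation reproduces an independent reference implementation to ≈1e-8
on matrices with asymmetric differential expression.

**Dispersion.** Per-gene dispersions maximize the Cox–Reid adjusted profile
likelihood (model log-likelihood minus half the log-determinant of the
Fisher information, removing most of the bias from estimating the mean
parameters). The APL is evaluated on a 25-point log-spaced grid from 1e-6
to 10, with IRLS refits warm-started along the grid and a parabolic
refinement of the argmax on the log axis. The common dispersion maximizes
the summed APL. Empirical-Bayes shrinkage interpolates log-dispersion
between gene-wise and common values with weight prior_df/(prior_df +
residual_df), prior_df = 10 by default — at the study's replication
(n = 2/condition, residual df = 4) this weights the common value ≈ 0.71,
which simulation shows keeps the test's type-I error near nominal. The
shrunk value always lies between the gene-wise and common estimates.

**Fitting.** Per-gene IRLS, vectorized across genes (batched weighted
least-squares solves), with step-halving on deviance increases, linear
predictor clipped to ±30, convergence when the relative deviance change
drops below 1e-8 or after 100 iterations; non-converged genes are flagged
and retained. All-zero genes sit at the lower boundary and are flagged
degenerate; they are never tested (class `filtered`).

**Tests.** Wald: contrast estimate over its standard error from the inverse
Fisher information, two-sided normal p. LRT: the design is rotated by an
orthonormal basis whose first vector is the (normalized) contrast, so the
hypothesis is exactly one coefficient; the reduced model drops that column
and the statistic is twice the log-likelihood difference against χ²(1).
Both routes report the same contrast estimate (they agree to ~1e-12 in
tests). BH adjustment excludes filtered (NaN) entries from the number of
tests.

## Differential expression

Genes with fewer than five total reads across all samples are removed before
anything else (the filter is deliberately upstream of normalization, so the
BH family equals the tested-gene count). Each knockdown is tested against
the shared control with median-of-ratios normalization and a Wald test.
Two significance conventions exist in practice for "twofold or higher
change": the default `fold2` mode requires |log2FC| ≥ 1, the alternative
`log2fc2` mode |log2FC| ≥ 2; both use FDR < 0.05, the mode is recorded in
the output, and the engine reports MLE (unshrunk) log2FCs.

## Translational efficiency

The four conditions are coded as cell means; the TE contrast on
(WT_I, KO_I, WT_P, KO_P) is (+1, −1, −1, +1). Normalization is TMM;
significance comes from the 1-df LRT. Classification defaults to raw
p < 0.05 on the sign of ΔTE, with an option to classify on the BH column
instead — both columns are always emitted. The low-count filter is applied
once to the pooled four-condition matrix, not per fraction. Exact
invariances hold for genotype-label swaps (ΔTE negates) and for the
Wald/LRT estimate identity; fraction-wide scaling is an invariance of the
estimand, and on literally rescaled counts (which are genuinely different NB
observations) the estimate is stable to ~1e-2 and FDR-based calls are
unchanged, which is what the tests assert.

## Overlap statistics

The randomization test redraws each set uniformly without replacement from
the universe, preserving set sizes, and counts iterations whose k-way
intersection reaches the observed one (ties count against significance);
the add-one pseudocount (x+1)/(n+1) prevents p = 0. The simulation uses
chained hypergeometric draws — the overlap of an independent uniform subset
with the running intersection is hypergeometric given that intersection's
size — which is distributionally identical to materializing the subsets and
makes 10⁶ iterations run in under a second; the equivalence is verified
against an exhaustive enumeration oracle on an 8-gene universe. The default
universe is the genes passing the low-count filter in the relevant
comparison. No expression- or length-matching is applied to the redrawn
sets. The pairwise hypergeometric test is the exact upper tail
P(X ≥ observed).

## Stage signatures

The NB regression treats each (signature gene, library) pair as one
observation, the group label as the sole predictor (genes are the
replicates; no per-gene random effects). TPM is continuous, so values are
rounded to the nearest integer before the count likelihood; this is recorded
in the result attributes. The fit is a Poisson GLM followed by a
method-of-moments dispersion estimate and an NB GLM at that fixed
dispersion; contrasts are Wald tests, BH-adjusted across the contrast
family. Profile classification calls a gene germ-cell-like when the mean of
GSC/CB/cyst is at least r× the whole-ovary level (r = 2 by default,
configurable), maternal-like for the reverse, flat otherwise; the rule is
invariant to per-gene rescaling.

## TOP motifs

The dominant TSS is the single modal CAGE 5′-end position within the window
around the annotated start — no tag clustering — with ties broken toward the
5′-most position (smallest coordinate on +, largest on −), favoring the
longest leader and therefore conservative for TOP detection. The classifier
requires a C/U first base and an initial pyrimidine run of at least
min_run = 5 counting the first base; the threshold follows the common
literature convention (C/U plus ≥4 further pyrimidines) since no universal
cutoff exists, and is configurable. Classification is case-insensitive and
T/U-equivalent.

## Chromatin marks

Coordinates are 0-based half-open throughout; tracks are contiguous
fixed-width bin tilings. RPKM = count·10⁹/(total reads · bin width). The
promoter is TSS ± 500 bp (strand-aware); promoter and body means are
overlap-weighted over bins. Differential calls use log2((KD + 1)/(WT + 1))
against a ±1 threshold, with the genome-wide median of the WT quantification
as the default background floor: losses additionally require WT above
background, gains KD above background, and genes under background in both
conditions are reported as `below_background` rather than stable.
Binarization is a Poisson upper tail (rate = genome-wide mean count per
bin) at p < 1e-4, and the redistribution index is
min(lost, gained)/max(lost, gained) over the 2×2 bin comparison. The
multi-state chromatin HMM segmentation used in some published workflows is
deliberately out of scope: the binarization-plus-2×2 comparison provides the
gain/loss semantics the downstream summaries need, without claiming
state-for-state concordance with any HMM. Meta-region matrices combine
fixed ±3 kb flanks at track resolution with a body rescaled to 100 columns
by linear interpolation; rows are sorted by log2FC within the
upregulated/nontarget/downregulated clusters (±1 log2FC boundaries).

## Synthetic data

The generators are pure functions of the configuration (seed included) and
write ground truth sufficient to score every stage. Defaults mirror the
study designs: two biological replicates per condition; log-normal baseline
means (median 500 reads, σ_log = 1) with NB noise at dispersion 0.05;
100-gene germ-cell (log2FC +2 in knockdowns) and maternal (−2) cohorts plus
per-genotype private cohorts so three-genotype overlaps have structure; a
100-gene TE cohort at ΔTE = ±2 with a 1.5× fraction-wide polysome scaling so
TMM is genuinely exercised; an 8× stage gradient; TOP leaders with runs of
5–14 pyrimidines and CAGE multinomials putting ~80% of tags on the planted
TSS; and mark tracks at 100-bp bins over 1 Mb with Poisson background rate
2, promoter peaks of +20, a 4× knockdown reduction on the loss cohort and a
mirrored gain cohort inside/outside ~20 random TADs.

What the harness emulates is the *statistical* structure the methods assume
— NB overdispersion, composition effects, fraction-wide scaling, peaked
CAGE tags, promoter-peaked marks. It does not emulate alignment artifacts,
GC or length bias, batch structure, correlated genes, isoform mixtures, or
TSS heterogeneity; passing recovery tests therefore demonstrates
correctness of the estimators under their assumed model, not robustness to
everything real libraries contain.

## Problem sizes and tolerances

Simulated checks run at 2000 genes (counts), 1000 genes (stages), 60–80
transcripts (CAGE), 10,000 bins/300 genes (marks) and 10⁶ randomization
iterations — sizes at which every documented recovery criterion is met with
margin while the whole suite stays fast. Monte-Carlo assertions use fixed
seeds; distributional checks use a KS distance of 0.05 against χ²(1) on
2000 null statistics; oracle equivalences use 1e-8 (TMM), 1e-12 (BH) and
exactness (hypergeometric enumeration).

## Known limitations

- Quasi-likelihood F-tests, trended dispersions, outlier-count handling and
  independent filtering are not implemented (by design).
- The stage regression inherits the "genes as replicates" assumption of the
  violin-plot analyses it mirrors; correlated genes would understate the
  standard errors.
- TSS calling uses the single modal position; dispersed promoters with
  multimodal CAGE signal can flip the called TSS between runs of similar
  height (the tie rule makes this deterministic but not necessarily
  biological).
- The TE fraction-scaling invariance holds exactly only for the estimand;
  see the translational-efficiency section.
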