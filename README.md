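# gc2mat

Analysis toolkit for the germ-cell-to-maternal transition in the *Drosophila*
ovary: how TORC1-dependent translation and ribosome levels feed into the
silencing of germ cell genes. The package re-implements, as a tested and
reusable pipeline, the computational stages that connect bulk RNA-seq of
germline knockdowns, polysome-profiling translational efficiency, gene-set
overlap statistics, stage-enriched expression signatures, TOP-motif calling
from CAGE transcription start sites, and differential chromatin-mark
summaries over genes and TADs. Every stage can be exercised end-to-end on
synthetic data with recorded ground truth.

It is written for computational biologists who want the statistical machinery
of this kind of study as a library — with explicit contracts, oracle-checked
numerics and a deterministic simulation harness — rather than as a one-off
collection of scripts.

## The models

**NB GLM engine.** Counts for gene *g* in library *j* are modelled as
negative binomial, *y*<sub>gj</sub> ~ NB(μ<sub>gj</sub>, α<sub>g</sub>) with
Var = μ + αμ², log μ<sub>gj</sub> = **x**<sub>j</sub>ᵀ**β**<sub>g</sub> +
o<sub>j</sub>, where the offset o<sub>j</sub> carries the normalization
(median-of-ratios size factors, or TMM-corrected library sizes). Dispersions
are estimated by Cox–Reid adjusted profile likelihood on a log grid and
shrunk toward the common dispersion with weight prior_df/(prior_df +
residual_df). Contrasts are tested by Wald statistics or by a 1-df
likelihood-ratio test after rotating the design so the contrast is a single
coefficient. Benjamini–Hochberg step-up controls the FDR.

**Differential expression** tests each knockdown genotype against the shared
control after excluding genes with fewer than five total reads, and calls a
gene up/down at FDR < 0.05 with a twofold change (`fold2`; a stricter
`log2fc2` mode requires |log2FC| ≥ 2).

**Translational efficiency (TE).** Polysome-seq samples map onto four
conditions (WT_Input, KO_Input, WT_Polysomes, KO_Polysomes); the genotype
effect on translation is the interaction contrast

```
ΔTE = (KO_Polysomes − KO_Input) − (WT_Polysomes − WT_Input)
```

tested by LRT after TMM normalization. The contrast cancels transcriptional
changes and any fraction-wide scaling.

**Overlap statistics.** k-way intersections are assessed by an empirical
randomization test (each of n iterations redraws every set uniformly from
the universe, preserving sizes; p = (exceedances + 1)/(n + 1)) and, pairwise,
by the upper-tail hypergeometric test.

**Stage signatures.** Signature-gene TPM across GSC-, CB-, cyst-enriched and
whole-ovary libraries is fit by NB regression with the group as sole
predictor; per-gene profiles are classed germ-cell-like or maternal-like by
a ratio rule between the undifferentiated stages and whole ovary.

**TOP motifs.** The dominant TSS is the modal CAGE 5′-end position
(ties break 5′-ward); a transcript is TOP when its leader starts with C/U
and opens with a pyrimidine run of ≥ 5 bases.

**Chromatin marks.** Binned CUT&RUN-style tracks are RPKM-normalized,
quantified over strand-aware promoter windows (TSS ± 500 bp) and gene
bodies, and compared between conditions with a log2 threshold over a
background floor; Poisson binarization plus a 2×2 bin comparison summarizes
genome-wide redistribution, and scale-regions matrices profile marks over
TADs with ±3 kb flanks.

## Worked example

```python
from gc2mat import SimulationConfig, simulate_polysome_experiment
from gc2mat import te

cfg = SimulationConfig(seed=1, n_genes=2000)     # 100 genes at ΔTE = ±2
counts, truth = simulate_polysome_experiment(cfg)
design = te.build_te_design(counts, wt="nosGAL4", ko="zfrp8_GKD")
table = te.run_te_analysis(counts, design)
print(te.classify_te(table))

m = table.merge(truth.table, on="gene_id")
cohort = m[m.cohort != "none"]
print("detected:", (cohort.pvalue < 0.05).mean())
print("median |error|:",
      (cohort.delta_te_log2 - cohort.true_delta_te_log2).abs().median())
```

prints

```
{'n_te_up': 96, 'n_te_down': 106, 'n_ns': 1798, 'n_filtered': 0}
detected: 1.0
median abs err: 0.3450671628901668
```

i.e. with two replicates per condition and median depth 500, every planted
±2-log2 TE shift reaches p < 0.05, the classification finds roughly the 50
up / 50 down designed genes plus the expected ~5% raw-p background among the
1900 null genes, and the median estimation error is ~0.35 log2 units.

The same stages are available from the shell:

```
gc2mat simulate --seed 1 --out data/
gc2mat de --counts data/counts.tsv --meta data/meta.tsv \
          --case zfrp8_GKD --control nosGAL4 --out de_zfrp8.tsv
gc2mat overlap --sets up_a.txt up_b.txt up_c.txt --universe tested.txt \
               --iters 1000000 --seed 0 --out overlap.json
gc2mat run --seed 1 --out full_run/
```

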