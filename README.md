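# fracloc

Analysis toolkit for **nucleocytoplasmic fractionation RNA-seq** (Frac-Seq)
and the matching fluorescence-microscopy readouts.  It is aimed at groups
studying nuclear RNA export: you deplete an export factor, sequence RNA from
nuclear, cytoplasmic and total fractions of knockdown and control cells, and
ask *which genes' RNAs became more nuclear, and what distinguishes those
genes' architecture* (pre-mRNA length, exon count, intronic content, 3'UTR
length).

## The statistic

For each gene *g*, a contrast pair of fractions (say N = nuclear,
C = cytoplasmic) and a knockdown condition, the localization change is a
log2 ratio of ratios,

```
Δ_g = log2( (N̄_g + p) / (C̄_g + p) )_KD  −  log2( (N̄_g + p) / (C̄_g + p) )_control
```

with N̄, C̄ size-factor-normalized (median-of-ratios) replicate means and a
prior count *p* (default 4).  A delta-method standard error se_g is
propagated from the replicate variances, and an empirical-Bayes normal
shrinkage pulls noisy estimates toward zero:

```
Δ̃_g = Δ_g · τ² / (τ² + se_g²),     τ² = max(0, Var(Δ) − mean(se²))
```

Positive Δ̃ means the gene's RNA became relatively more nuclear after the
knockdown.  Genes enter the analysis only if their mean FPKM across all
samples exceeds 1 and they are not mitochondrial.

Downstream, Δ̃ is related to gene architecture with Spearman rank
correlations, pre-mRNA length bins (<10, 10–20, 20–30, 30–40, 40–50,
>50 kb), single/multi-exon classes and arbitrary gene sets, using
Mann–Whitney–Wilcoxon tests (exact by enumeration for small untied samples)
with Benjamini–Hochberg FDR adjustment — all implemented in
`fracloc.strata` from first principles.  `fracloc.imaging` adds the
microscopy quantifications: cytoplasmic/total RNA ratios, area-constrained
nuclear-speckle segmentation (threshold set so 10% ± 0.5% of the nuclear
area is selected), brightest-speckle Pearson correlation, smFISH spot
detection/classification, and knockdown/control decay-ratio time courses.

Everything is exercisable without external data: `fracloc.simdata`
generates a seeded toy annotation (writable as GTF), negative-binomial
fractionation counts in which the knockdown shifts the nuclear share by
`β_L·exp(−L/λ_L) + β_E·[single-exon]`, and two-channel synthetic cell
images — each with recorded ground truth.

## Worked example

```python
from fracloc import (
    make_toy_annotation, gene_metrics_table, simulate_fracseq_counts,
    LocalizationModel, feature_correlations,
)

ann = make_toy_annotation(seed=1)                 # 2000 genes, 6 classes
gm = gene_metrics_table(ann)                      # per-gene architecture medians
exp = simulate_fracseq_counts(ann, seed=2)        # NB counts, default effect
model = LocalizationModel(exp, exonic_lengths=gm["exonic_length"],
                          chromosomes=gm["chromosome"])
res = model.fit(contrast=("nuclear", "cytoplasmic"), kd_condition="KD_A")
print(res.summary())
```

```
Localization change results
===========================
contrast:        log2(nuclear/cytoplasmic)
knockdown:       KD_A vs control
genes retained:  1953
prior count:     4.0
tau^2 (prior):   1.2264
mean delta_raw:  +0.1688
median delta:    -0.0445
delta IQR:       [-0.6286, +0.8003]
```

1953 of 2000 genes survive the expression and mitochondrial filters; the
positive mean delta reflects the planted export defect (many short genes
became more nuclear).  Correlating the shrunken deltas with architecture:

```python
print(feature_correlations(res.table, gm))
```

```
           metric       rho             p    n
      gene_length -0.833769  0.000000e+00 1953
  pre_mrna_length -0.916636  0.000000e+00 1953
    exonic_length -0.871871  0.000000e+00 1953
          n_exons -0.405512  3.442442e-78 1953
fraction_intronic -0.262604  3.654533e-32 1953
     exon_density  0.508021 1.203850e-128 1953
      utr3_length -0.856856  0.000000e+00 1704
```

The strong negative rank correlation with pre-mRNA length is the planted
signature: short genes depend most on the depleted export factor.  The
same pipeline runs from the shell:

```sh
fracloc run-all --seed 1 --outdir run1        # full synthetic experiment
fracloc annofeat annotation.gtf --out gene_metrics.tsv
fracloc locstats counts.tsv design.tsv --metrics gene_metrics.tsv --kd KD_A
```

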