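# Methods

This note documents the models, estimators and design choices behind
`fracloc`, in the order data flows through the package.

## Annotation model and architecture metrics (`fracloc.annotation`)

GTF files are 1-based with closed intervals; internally every interval is
0-based half-open so that `length = end - start` with no off-by-one
ambiguity.  The conversion happens only at the file boundary and is covered
by a write→read round-trip test.  Parsing goes through `gffutils` with an
in-memory database; the writer emits the GENCODE attribute dialect
(`gene_id`, `transcript_id`, `gene_type`).

Per transcript: pre-mRNA length is the genomic span including introns;
exonic (mature) length the sum of exon lengths; fraction intronic
`(span − exonic)/span`; exon density `n_exons/exonic_length`; 3'UTR length
the exonic distance from the stop-codon-adjacent CDS end to the transcript
3' end, undefined (not zero) for transcripts without CDS records.  Gene
level values are unweighted medians across the gene's transcripts (the
average of the middle two for even counts).  A gene is *single-exon* only
when its median exon count is exactly 1 before rounding; the rounded exon
count used for stratification rounds half-integers away from zero.  "Gene
length" is the span from the minimum transcript start to the maximum
transcript end.  Length bins are left-closed/right-open on the kb
boundaries (<10, 10–20, 20–30, 30–40, 40–50, >50 kb), so exactly 10,000 nt
falls in the 10–20 kb bin.

## Synthetic data generator (`fracloc.simdata`)

The generator emulates the *inputs* of a fractionation study, not its raw
reads: no sequences, alignments or FASTQ are simulated, only per-gene
counts and images.

**Annotation.** Six gene-class templates (2000 genes by default) span the
architecture extremes that matter for export analysis: `histone_like`
(~0.8 kb, intronless, protein-coding), `ribosomal_like` (~4 kb, several
short exons), `long_multiexon` (lognormal around 25 kb so the genome-wide
median pre-mRNA lands near the ~21 kb seen in real annotations),
`lncRNA_single` and `lncRNA_multi`, and `mito` genes on a dedicated `chrM`
so the mitochondrial exclusion filter is exercisable.  Spans are lognormal;
exon counts are 1 + Poisson; exon/intron boundaries tile the span with
gamma-weighted segments of at least 1 nt.  Protein-coding transcripts carry
CDS records occupying the middle of the mature transcript so 3'UTR lengths
are defined.

**Counts.** Per gene, a baseline expression `mu_g ~ lognormal(log 200, 1)`
(counts at unit depth) is drawn once.  The knockdown shifts the expected
log2(N/C) by

```
shift_g = beta_L * exp(-L_g / lambda_L) + beta_E * [single-exon]
```

applied on the logit of the nuclear share (scaled by ln 2), starting from a
baseline nuclear share of logistic(−0.4) ≈ 0.40.  Defaults:
`beta_L = 3.5` log2 units and `lambda_L = 20 kb`, chosen so the
most-affected class (short intronless genes) shifts ≈ 4 log2 units — the
magnitude of the strongest shifts in fractionation studies of export-factor
depletion — and so the generator satisfies its stated calibration property
(rank correlation > 0.9 between the shrunken estimates and the true shift
at the default problem size); `beta_E = 1.0` adds a single-exon-specific
defect.  Nuclear and cytoplasmic counts are drawn *independently* per
fraction (fractions are separate libraries, as in the lab protocol), not
multinomially from a shared pool, as NB with `Var = mu + alpha mu^2`,
`alpha = 0.05` (typical bulk RNA-seq overdispersion); per-sample depth
factors are lognormal (sd 0.15).  `lnc_destab = 0.7` multiplies lncRNA
expression in knockdown conditions in *all* fractions — destabilization
lowers nuclear and cytoplasmic levels alike and leaves N/C untouched.
Intron-assigned counts are emitted with a constant per-gene unspliced
fraction (`0.5 × fraction_intronic`), identical across conditions, so the
cytoplasmic intronic read fraction is condition-invariant by construction.
Replicates default to 3 per fraction × condition (configurable; the design
requires at least 2).  All randomness flows from the single seed.

What the generator does **not** emulate: GC/length-dependent coverage bias,
isoform switching, batch effects, correlated genes, and mapping ambiguity.
Passing tests therefore demonstrate estimator correctness and calibration
under the stated generative model, not robustness to those real-data
artifacts.

**Images.** Cell and nucleus are nested ellipses (192×192 px default,
nucleus ≈ 5,500 px).  The speckle-marker channel is a nucleoplasmic
baseline plus 10 Gaussian foci (σ 2.5 px) placed inside the nucleus with a
margin; the RNA channel is a weighted mixture of the speckle field, uniform
nucleoplasm and uniform cytoplasm, plus optional diffraction-limited spots
(σ 1.2 px) planted at recorded coordinates with a minimum separation of
5 px (spots are non-overlapping by construction).  Noise is Poisson on
photon counts scaled by a gain parameter — the standard fluorescence model,
which keeps intensities non-negative.  Placement is rejection sampling with
a bounded attempt budget; exhausting it raises an error.

## Localization estimator (`fracloc.localization`)

The estimator is deliberately simple and fully self-contained: normalized
replicate means with a prior count, log2 ratio-of-ratios, delta-method
standard errors, and empirical-Bayes normal shrinkage toward zero
(method-of-moments prior variance `tau² = max(0, Var(Δ) − mean(se²))`).
The shrunken estimate never changes sign and never increases magnitude;
`tau² → ∞` recovers the raw delta.  Under a global null `tau²` is floored
at zero and every shrunken delta degenerates to exactly 0 — null
calibration checks therefore read the raw deltas.

Numerical choices: prior count 4; size factors by median-of-ratios over
genes with nonzero counts in every sample (an informative error advises a
pseudocount when none exists); the FPKM filter mean is taken over all
samples of all fractions and conditions, with a strict `> 1` inequality;
the three contrast pairs (N/C, N/T, C/T) are treated independently.  The
per-gene squared CV of a replicate mean uses the per-gene variance when at
least 3 replicates exist and the across-gene median otherwise (a 1-d.f.
variance is too noisy to use alone).

## Stratified testing (`fracloc.strata`)

Spearman's rho uses mid-rank ties; p values come from exact permutation
enumeration for n ≤ 8 and the t approximation otherwise.  The
Mann–Whitney U test is exact by dynamic-programming enumeration for
combined n ≤ 12 without ties (two-sided p = 2·min(lower, upper) tail,
capped at 1) and otherwise uses the normal approximation with tie and
continuity corrections.  Benjamini–Hochberg is the standard step-up.

Families for BH adjustment span all tests within one report section — the
choice is conservative and reproducible.  Each-vs-background group
contrasts exclude the group from its background to avoid overlap
dependence.  The length-controlled exon analysis tests, within each narrow
length window (5–6 kb, 20–25 kb by default), every pair of occupied
(rounded) exon-count groups with ≥ 5 members, plus matched between-window
comparisons per exon count and one pooled matched-exon between-window
comparison (pooling restores power when individual matched counts are
sparse).  Reports are pure functions of their inputs; TSV serialization is
byte-deterministic.  Both raw p and BH-adjusted q are emitted throughout.

## Image quantification (`fracloc.imaging`)

All intensity-ratio outputs are invariant to uniform rescaling.  Background
subtraction defaults to the median intensity outside the cell mask, clipped
at zero.  Speckle segmentation thresholds the SC35 channel at the
(1 − target) quantile of nuclear intensities and accepts the result if the
achieved area fraction is within the tolerance (target 10%, tolerance
0.5%); when ties straddle the window (e.g. a constant image), tied pixels
are admitted in flat pixel-index order — deterministic, with a warning.
Speckles are ranked by *peak* (not integrated) component intensity;
Pearson ROIs are the component pixels plus a 1-pixel dilation border to
include speckle edges; components under 4 px are skipped.  Aggregation is
mean of cell means, then mean across experiments.

Spot detection is a documented stand-in operator (the field typically
defers to external tools): a white top-hat with a disk of radius three
smoothing scales removes everything wider than a spot — compartment
baselines and their step edges included (a plain band-pass filter leaves
ridge artifacts along the curved cell boundary) — followed by a Gaussian
smooth and local-maximum extraction above median + 5 robust SDs, with
minimum separation of two smoothing scales.  A spot is nuclear iff its
center pixel is in the nucleus mask; no sub-pixel interpolation.  The decay
time course is the per-timepoint ratio of condition means with a
first-order propagated SE (undefined for single-cell timepoints).

## Pipeline (`fracloc.pipeline`, `fracloc.cli`)

One flat config (YAML) drives generate → features → localization → strata →
imaging.  The manifest records the package version, seed and a hash of the
analysis parameters (the output path is excluded from the hash); reruns
with the same config produce byte-identical TSVs.  Stage wall times are
logged for information only.

## Problem sizes

The default study conditions are 2000 genes, 3 replicates per
fraction × condition, and 192×192 px images; null-calibration checks use
100 seeded re-simulations of the count stage on a fixed annotation.  These
sizes make every distributional property measurable (e.g. standard error of
a mean delta ≈ 0.01 log2 units) while a full test run completes in well
under a minute of simulation time.

## Known limitations

* The shrinkage estimator is a simple normal-normal EB scheme, not a
  count-model posterior; very low-count genes rely on the prior count
  rather than a mean-variance trend.
* 3'UTR length is undefined for non-coding transcripts and skipped in gene
  medians, so UTR correlations run on the coding subset.
* The spot detector assumes diffraction-limited, non-overlapping spots on
  slowly varying backgrounds; dense spot fields will undercount.
* No cell/nucleus segmentation from raw micrographs: masks are inputs.
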