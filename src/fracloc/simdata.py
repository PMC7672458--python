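"""Seeded synthetic data: annotation, fractionation counts, and cell images.

Every downstream stage of the package is testable without external downloads
because this module fabricates the three kinds of input the analyses need,
each with recorded ground truth:

* a toy gene annotation whose gene classes mimic the architecture extremes
  seen in real transcriptomes (short intronless histone-like genes, compact
  multi-exon ribosomal-like genes, long multi-exon genes, single- and
  multi-exon lncRNAs, and mitochondrial genes on a dedicated ``chrM``);
* negative-binomial count matrices for {nuclear, cytoplasmic, total}
  fractions x {control, KD_A, KD_D} conditions, where the knockdown shifts a
  gene's nuclear share by an amount decaying with pre-mRNA length plus an
  extra bump for single-exon genes — the architecture-dependent export
  defect the statistics downstream are built to detect;
* two-channel fluorescence cell images (speckle-marker channel + RNA
  channel) with nested elliptical nucleus/cell masks, planted speckle foci
  and diffraction-limited RNA spots.

All randomness flows from the single ``seed`` argument of each generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    MITO_CHROM,
    AnnotationSet,
    Exon,
    Gene,
    Transcript,
    gene_metrics_table,
)

__all__ = [
    "GeneClassTemplate",
    "EffectModel",
    "FracSeqExperiment",
    "CellImage",
    "SpeckleImageParams",
    "default_templates",
    "make_toy_annotation",
    "simulate_fracseq_counts",
    "simulate_cell_image",
]

FRACTIONS = ("nuclear", "cytoplasmic", "total")
CONDITIONS = ("control", "KD_A", "KD_D")
KD_CONDITIONS = ("KD_A", "KD_D")

LN2 = math.log(2.0)


class ConfigurationError(ValueError):
    """Invalid generator template or effect-model parameter."""


class DesignError(ValueError):
    """Invalid experimental design (e.g. too few replicates)."""


# ---------------------------------------------------------------------------
# Templates


#: distribution laws are (kind, *params): ("fixed", k) or ("poisson1", lam)
#: meaning 1 + Poisson(lam) (so the support starts at 1).
_FORCED_SINGLE_EXON = {"histone_like", "lncRNA_single"}


@dataclass(frozen=True)
class GeneClassTemplate:
    """Parameters of one synthetic gene class."""

    name: str
    span_log_mean: float          # lognormal params of pre-mRNA span (nt)
    span_log_sd: float
    exon_count_law: tuple = ("fixed", 1)
    transcripts_per_gene_law: tuple = ("fixed", 1)
    biotype: str = "protein_coding"
    chromosome_pool: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4")

    def validate(self) -> None:
        if self.span_log_sd < 0:
            raise ConfigurationError(f"template {self.name}: span_log_sd must be >= 0")
        if not np.isfinite(self.span_log_mean):
            raise ConfigurationError(f"template {self.name}: span_log_mean must be finite")
        for law_name in ("exon_count_law", "transcripts_per_gene_law"):
            law = getattr(self, law_name)
            if law[0] not in ("fixed", "poisson1"):
                raise ConfigurationError(f"template {self.name}: unknown {law_name} {law[0]!r}")
            if law[0] == "fixed" and law[1] < 1:
                raise ConfigurationError(f"template {self.name}: {law_name} fixed value must be >= 1")
            if law[0] == "poisson1" and law[1] < 0:
                raise ConfigurationError(f"template {self.name}: {law_name} rate must be >= 0")
        if self.biotype not in ("protein_coding", "lncRNA"):
            raise ConfigurationError(f"template {self.name}: biotype must be protein_coding or lncRNA")
        if not self.chromosome_pool:
            raise ConfigurationError(f"template {self.name}: chromosome_pool is empty")
        if self.name in _FORCED_SINGLE_EXON and self.exon_count_law != ("fixed", 1):
            raise ConfigurationError(
                f"template {self.name}: exon_count_law must be ('fixed', 1) for this class"
            )


def default_templates() -> list[tuple[GeneClassTemplate, int]]:
    """Default gene-class mix: 2000 genes spanning the architecture extremes.

    Spans are lognormal; medians chosen to resemble the real classes they
    mimic (histone genes ~0.8 kb intronless, ribosomal-protein genes a few
    kb with several short introns, typical multi-exon genes tens of kb —
    the genome-wide median pre-mRNA is ~21 kb).
    """
    return [
        (GeneClassTemplate("histone_like", math.log(800), 0.25), 60),
        (
            GeneClassTemplate(
                "ribosomal_like", math.log(4000), 0.4, exon_count_law=("poisson1", 4.0),
                transcripts_per_gene_law=("poisson1", 0.7),
            ),
            150,
        ),
        (
            GeneClassTemplate(
                "long_multiexon", math.log(25_000), 0.9, exon_count_law=("poisson1", 8.0),
                transcripts_per_gene_law=("poisson1", 1.0),
            ),
            1500,
        ),
        (
            GeneClassTemplate("lncRNA_single", math.log(3000), 0.6, biotype="lncRNA"),
            100,
        ),
        (
            GeneClassTemplate(
                "lncRNA_multi", math.log(15_000), 0.8, exon_count_law=("poisson1", 2.0),
                biotype="lncRNA",
            ),
            150,
        ),
        (
            GeneClassTemplate(
                "mito", math.log(1200), 0.3, chromosome_pool=(MITO_CHROM,)
            ),
            40,
        ),
    ]


def _draw_law(law: tuple, rng: np.random.Generator) -> int:
    if law[0] == "fixed":
        return int(law[1])
    return 1 + int(rng.poisson(law[1]))


def _partition_span(span: int, n_exons: int, rng: np.random.Generator) -> list[Exon]:
    """Split [0, span) into n exons separated by n-1 introns, each >= 1 nt."""
    n_seg = 2 * n_exons - 1
    if span < n_seg:
        n_exons = max(1, (span + 1) // 2)
        n_seg = 2 * n_exons - 1
    # exons get ~60% of the span weight on average for small genes; introns
    # dominate once many segments exist (as in real genes)
    w = rng.gamma(1.0, 1.0, size=n_seg)
    lengths = np.maximum(1, np.floor(w / w.sum() * (span - n_seg)).astype(int) + 1)
    # fix rounding so the segments tile the span exactly
    lengths[-1] += span - int(lengths.sum())
    if lengths[-1] < 1:  # borrow from the largest segment
        deficit = 1 - lengths[-1]
        j = int(np.argmax(lengths[:-1]))
        lengths[j] -= deficit
        lengths[-1] = 1
    exons, pos = [], 0
    for i, L in enumerate(lengths):
        if i % 2 == 0:
            exons.append(Exon(pos, pos + int(L)))
        pos += int(L)
    return exons


def _cds_for(exons: list[Exon], strand: str, rng: np.random.Generator) -> list[Exon]:
    """CDS occupying the middle of the mature transcript (5' and 3' UTRs left)."""
    exonic = sum(e.length for e in exons)
    if exonic < 30:
        return []
    utr5 = max(1, int(0.10 * exonic))
    utr3 = max(1, int(round((0.15 + 0.15 * rng.random()) * exonic)))
    lo, hi = utr5, exonic - utr3  # CDS in mature coords, 5'->3'
    if hi - lo < 3:
        return []
    if strand == "-":
        lo, hi = exonic - hi, exonic - lo  # convert to genomic-orientation offsets
    cds, off = [], 0
    for e in exons:
        a, b = max(lo, off), min(hi, off + e.length)
        if b > a:
            cds.append(Exon(e.start + (a - off), e.start + (b - off)))
        off += e.length
    return cds


def make_toy_annotation(
    templates: Sequence[tuple[GeneClassTemplate, int]] | None = None,
    seed: int = 0,
) -> AnnotationSet:
    """Generate a deterministic toy annotation from gene-class templates.

    Genes are placed non-overlapping along the chromosomes of each
    template's pool; exons lie within the transcript span, sorted and
    non-overlapping, and protein-coding transcripts carry CDS records so
    3'UTR lengths are defined.
    """
    if templates is None:
        templates = default_templates()
    for tpl, count in templates:
        tpl.validate()
        if count < 0:
            raise ConfigurationError(f"template {tpl.name}: count must be >= 0")
    rng = np.random.default_rng(seed)
    cursors: dict[str, int] = {}
    genes: list[Gene] = []
    gidx = 0
    for tpl, count in templates:
        for _ in range(count):
            gidx += 1
            gene_id = f"G{gidx:05d}_{tpl.name}"
            chrom = tpl.chromosome_pool[int(rng.integers(len(tpl.chromosome_pool)))]
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = _draw_law(tpl.transcripts_per_gene_law, rng)
            start = cursors.get(chrom, 0) + int(rng.integers(500, 5000))
            gene = Gene(gene_id=gene_id, chrom=chrom, strand=strand, biotype=tpl.biotype)
            for ti in range(n_tx):
                span = max(200, int(round(rng.lognormal(tpl.span_log_mean, tpl.span_log_sd))))
                n_exons = _draw_law(tpl.exon_count_law, rng)
                exons = [Exon(start + e.start, start + e.end) for e in _partition_span(span, n_exons, rng)]
                tx = Transcript(
                    transcript_id=f"{gene_id}.T{ti + 1}",
                    start=exons[0].start,
                    end=exons[-1].end,
                    exons=exons,
                )
                if tpl.biotype == "protein_coding":
                    tx.cds = _cds_for(exons, strand, rng)
                tx.validate()
                gene.transcripts.append(tx)
            genes.append(gene)
            cursors[chrom] = gene.end
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return AnnotationSet(genes)


# ---------------------------------------------------------------------------
# Fractionation count simulation


@dataclass(frozen=True)
class EffectModel:
    """Generative model of the knockdown's effect on nuclear/cytoplasmic split.

    In knockdown conditions a gene's expected log2(N/C) shifts by
    ``beta_L * exp(-L/lambda_L) + beta_E * [single-exon]`` — largest for
    short genes, decaying with pre-mRNA length L, plus an additive bump for
    single-exon genes.  The shift is applied on the logit of the nuclear
    share (scaled by ln 2 so the log2 ratio moves by the stated amount).
    ``lnc_destab`` multiplies lncRNA expression in knockdown conditions
    (modelling their destabilization, visible in all fractions).
    """

    beta_L: float = 3.5                 # max localization shift, log2 units
    lambda_L: float = 20_000.0          # length decay scale, nt
    beta_E: float = 1.0                 # extra shift for single-exon genes, log2 units
    lnc_destab: float = 0.7             # expression multiplier for lncRNAs in KD
    base_logit_nuclear: float = -0.4    # baseline nuclear share on logit scale
    dispersion: float = 0.05            # NB alpha, Var = mu + alpha mu^2
    depth_law: tuple = ("lognormal", 0.0, 0.15)  # per-sample depth factor
    mu_log_mean: float = math.log(200.0)  # per-gene baseline expression (counts)
    mu_log_sd: float = 1.0
    unspliced_coef: float = 0.5         # unspliced fraction = coef * fraction_intronic

    def validate(self) -> None:
        if self.lambda_L <= 0:
            raise ConfigurationError("lambda_L must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.lnc_destab <= 0:
            raise ConfigurationError("lnc_destab must be positive")
        if not (0 <= self.unspliced_coef < 1):
            raise ConfigurationError("unspliced_coef must be in [0, 1)")
        for v in (self.beta_L, self.beta_E, self.base_logit_nuclear):
            if not np.isfinite(v):
                raise ConfigurationError("effect parameters must be finite")

    def shift(self, pre_mrna_length: np.ndarray, single_exon: np.ndarray) -> np.ndarray:
        """Expected knockdown log2(N/C) shift per gene."""
        return self.beta_L * np.exp(-np.asarray(pre_mrna_length) / self.lambda_L) + (
            self.beta_E * np.asarray(single_exon, dtype=float)
        )


def null_effect() -> EffectModel:
    """Effect model with no localization or expression effect."""
    return EffectModel(beta_L=0.0, beta_E=0.0, lnc_destab=1.0)


@dataclass
class FracSeqExperiment:
    """Count matrices plus the sample design of a fractionation experiment."""

    counts: pd.DataFrame                 # genes x samples, integer
    design: pd.DataFrame                 # index sample; fraction, condition, replicate
    intronic_counts: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None    # per-gene generative parameters

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            raise DesignError("counts must be non-negative")
        if self.design.index.duplicated().any():
            raise DesignError("design sample labels must be unique")
        reps = self.design.groupby(["fraction", "condition"]).size()
        if (reps < 2).any():
            bad = reps[reps < 2].index.tolist()
            raise DesignError(f"every (fraction, condition) needs >= 2 replicates; short: {bad}")

    def samples(self, fraction: str | None = None, condition: str | None = None) -> list[str]:
        d = self.design
        if fraction is not None:
            d = d[d["fraction"] == fraction]
        if condition is not None:
            d = d[d["condition"] == condition]
        return list(d.index)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if alpha <= 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_fracseq_counts(
    annotation: AnnotationSet,
    effect: EffectModel | None = None,
    replicates: int = 3,
    seed: int = 0,
    conditions: Sequence[str] = CONDITIONS,
) -> FracSeqExperiment:
    """Simulate NB counts for all fractions x conditions x replicates.

    Per gene, a baseline expression mu_g is drawn once.  Nuclear and
    cytoplasmic libraries are drawn independently (they are separate
    libraries in the lab protocol) with means ``depth * mu_g * 2 p_g`` and
    ``depth * mu_g * 2 (1 - p_g)`` where p_g is the nuclear share; total
    libraries have mean ``depth * mu_g``.  Intron-assigned counts are
    emitted with a constant per-gene unspliced fraction across conditions.
    Ground truth (mu, shares, the true log2(N/C) shift) is recorded.
    """
    if effect is None:
        effect = EffectModel()
    effect.validate()
    if replicates < 2:
        raise DesignError(f"replicates must be >= 2, got {replicates}")
    if len(annotation) == 0:
        raise DesignError("annotation is empty")
    if "control" not in conditions:
        raise DesignError("conditions must include 'control'")

    rng = np.random.default_rng(seed)
    gm = gene_metrics_table(annotation)
    genes = gm.index.to_numpy()
    n_genes = len(genes)
    L = gm["pre_mrna_length"].to_numpy(float)
    single = (gm["exon_class"] == "single").to_numpy()
    is_lnc = (gm["biotype"] == "lncRNA").to_numpy()
    frac_intronic = gm["fraction_intronic"].to_numpy(float)

    mu = rng.lognormal(effect.mu_log_mean, effect.mu_log_sd, size=n_genes)
    shift = effect.shift(L, single)
    base = effect.base_logit_nuclear
    p_ctrl = 1.0 / (1.0 + np.exp(-base))
    p_kd = 1.0 / (1.0 + np.exp(-(base + shift * LN2)))

    u = np.clip(effect.unspliced_coef * frac_intronic, 0.0, 0.95)
    intron_factor = u / (1.0 - u)

    kind, d_mean, d_sd = effect.depth_law
    if kind != "lognormal":
        raise ConfigurationError(f"unknown depth_law kind {kind!r}")

    cols, design_rows = {}, []
    intronic_cols = {}
    for cond in conditions:
        is_kd = cond != "control"
        p = p_kd if is_kd else np.full(n_genes, p_ctrl)
        destab = np.where(is_lnc & is_kd, effect.lnc_destab, 1.0)
        mu_cond = mu * destab
        for frac in FRACTIONS:
            if frac == "nuclear":
                mean_g = mu_cond * 2.0 * p
            elif frac == "cytoplasmic":
                mean_g = mu_cond * 2.0 * (1.0 - p)
            else:
                mean_g = mu_cond
            for r in range(1, replicates + 1):
                depth = rng.lognormal(d_mean, d_sd)
                sample = f"{frac}_{cond}_r{r}"
                cols[sample] = _nb_draw(rng, depth * mean_g, effect.dispersion)
                intronic_cols[sample] = _nb_draw(
                    rng, depth * mean_g * intron_factor, effect.dispersion
                )
                design_rows.append(
                    {"sample": sample, "fraction": frac, "condition": cond, "replicate": r}
                )

    counts = pd.DataFrame(cols, index=genes)
    intronic = pd.DataFrame(intronic_cols, index=genes)
    design = pd.DataFrame(design_rows).set_index("sample")
    truth = pd.DataFrame(
        {
            "mu": mu,
            "p_control": p_ctrl,
            "p_kd": p_kd,
            "true_shift": shift,
            "single_exon": single,
            "biotype": gm["biotype"].to_numpy(),
            "pre_mrna_length": L,
        },
        index=genes,
    )
    exp = FracSeqExperiment(counts=counts, design=design, intronic_counts=intronic, truth=truth)
    exp.validate()
    return exp


# ---------------------------------------------------------------------------
# Synthetic two-channel cell images


@dataclass(frozen=True)
class SpeckleImageParams:
    """Configuration of the synthetic two-channel cell image.

    The speckle-marker channel (``sc35``) is a nucleoplasmic baseline plus
    Gaussian foci inside the nucleus; the RNA channel is a weighted mixture
    of the speckle field, uniform nucleoplasm and uniform cytoplasm, plus
    optional diffraction-limited spots.  Noise is Poisson on photon counts
    (scaled by ``gain``), the standard fluorescence model.
    """

    shape: tuple[int, int] = (192, 192)
    cell_radii: tuple[float, float] = (88.0, 70.0)
    nucleus_radii: tuple[float, float] = (46.0, 38.0)
    n_speckles: int = 10
    speckle_sigma: float = 2.5
    speckle_amp: float = 400.0
    nucleoplasm_level: float = 60.0
    cyto_level: float = 25.0
    w_spec: float = 1.0
    w_nuc: float = 1.0
    w_cyt: float = 1.0
    n_nuclear_spots: int = 0
    n_cyto_spots: int = 0
    spot_amp: float = 300.0
    spot_sigma: float = 1.2
    spot_min_separation: float = 5.0  # planted spots are non-overlapping
    baseline: float = 8.0
    gain: float = 1.0
    max_attempts: int = 200

    def validate(self) -> None:
        if self.shape[0] < 64 or self.shape[1] < 64:
            raise ConfigurationError("image dimensions must be >= 64x64")
        if self.n_speckles < 0:
            raise ConfigurationError("n_speckles must be >= 0")
        if self.gain <= 0:
            raise ConfigurationError("gain must be positive")


@dataclass
class CellImage:
    sc35: np.ndarray
    rna: np.ndarray
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.sc35.shape == self.rna.shape == self.nucleus_mask.shape == self.cell_mask.shape):
            raise ConfigurationError("channels and masks must share one shape")
        if (self.nucleus_mask & ~self.cell_mask).any():
            raise ConfigurationError("nucleus_mask must be contained in cell_mask")

    def save(self, outdir, prefix: str = "cell") -> None:
        """Write channels as 16-bit grayscale TIFFs and masks as 8-bit TIFFs.

        Intensities are rounded and clipped to the uint16 range; spot and
        speckle truth coordinates go to ``<prefix>_truth.tsv``.
        """
        import os

        import pandas as pd
        import tifffile

        os.makedirs(outdir, exist_ok=True)
        for name, arr in (("sc35", self.sc35), ("rna", self.rna)):
            data = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
            tifffile.imwrite(os.path.join(outdir, f"{prefix}_{name}.tif"), data)
        for name, arr in (("nucleus_mask", self.nucleus_mask), ("cell_mask", self.cell_mask)):
            tifffile.imwrite(os.path.join(outdir, f"{prefix}_{name}.tif"),
                             arr.astype(np.uint8))
        rows = []
        for kind, key in (("speckle", "speckle_centers"), ("nuclear_spot", "nuclear_spots"),
                          ("cytoplasmic_spot", "cytoplasmic_spots")):
            for y, x in np.asarray(self.truth.get(key, np.empty((0, 2)))).reshape(-1, 2):
                rows.append({"kind": kind, "row": int(y), "col": int(x)})
        pd.DataFrame(rows, columns=["kind", "row", "col"]).to_csv(
            os.path.join(outdir, f"{prefix}_truth.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, outdir, prefix: str = "cell") -> "CellImage":
        """Read a :meth:`save` directory back into a CellImage (truth coords only)."""
        import os

        import pandas as pd
        import tifffile

        def rd(name):
            return tifffile.imread(os.path.join(outdir, f"{prefix}_{name}.tif"))

        truth: dict = {}
        tpath = os.path.join(outdir, f"{prefix}_truth.tsv")
        if os.path.exists(tpath):
            tt = pd.read_csv(tpath, sep="\t")
            for kind, key in (("speckle", "speckle_centers"), ("nuclear_spot", "nuclear_spots"),
                              ("cytoplasmic_spot", "cytoplasmic_spots")):
                sub = tt[tt["kind"] == kind]
                truth[key] = sub[["row", "col"]].to_numpy(int).reshape(-1, 2)
        img = cls(
            sc35=rd("sc35").astype(float),
            rna=rd("rna").astype(float),
            nucleus_mask=rd("nucleus_mask").astype(bool),
            cell_mask=rd("cell_mask").astype(bool),
            truth=truth,
        )
        img.validate()
        return img


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2 <= 1.0


def _sample_in_mask(mask: np.ndarray, rng: np.random.Generator, n: int, max_attempts: int,
                    margin_mask: np.ndarray | None = None,
                    min_separation: float = 0.0,
                    existing: np.ndarray | None = None) -> np.ndarray:
    """Rejection-sample n integer coordinates inside mask (bounded attempts)."""
    target = mask if margin_mask is None else margin_mask
    coords: list[tuple[int, int]] = []
    placed = [] if existing is None else [tuple(p) for p in existing]
    attempts = 0
    h, w = mask.shape
    while len(coords) < n:
        attempts += 1
        if attempts > max_attempts * max(1, n):
            raise ConfigurationError("could not place points inside mask within attempt budget")
        y = int(rng.integers(h))
        x = int(rng.integers(w))
        if not target[y, x]:
            continue
        if min_separation > 0 and any(
            (y - py) ** 2 + (x - px) ** 2 < min_separation**2 for py, px in placed
        ):
            continue
        coords.append((y, x))
        placed.append((y, x))
    return np.array(coords, dtype=int).reshape(-1, 2)


def _gaussian_field(shape, centers, sigma, amp) -> np.ndarray:
    out = np.zeros(shape, dtype=float)
    if len(centers) == 0:
        return out
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for (cy, cx) in centers:
        out += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
    return out


def simulate_cell_image(params: SpeckleImageParams | None = None, seed: int = 0) -> CellImage:
    """Generate one synthetic two-channel cell with ground truth."""
    if params is None:
        params = SpeckleImageParams()
    params.validate()
    rng = np.random.default_rng(seed)
    h, w = params.shape
    center = (h / 2.0, w / 2.0)
    cell_mask = _ellipse_mask(params.shape, center, params.cell_radii)
    nucleus_mask = _ellipse_mask(params.shape, center, params.nucleus_radii)
    nucleus_mask &= cell_mask

    # keep foci away from the nuclear rim so they sit fully inside
    inner = _ellipse_mask(
        params.shape,
        center,
        (params.nucleus_radii[0] - 3 * params.speckle_sigma,
         params.nucleus_radii[1] - 3 * params.speckle_sigma),
    )
    speckle_centers = _sample_in_mask(
        nucleus_mask, rng, params.n_speckles, params.max_attempts, margin_mask=inner
    )
    speckle_field = _gaussian_field(params.shape, speckle_centers, params.speckle_sigma, params.speckle_amp)

    sc35 = params.baseline + params.nucleoplasm_level * nucleus_mask + speckle_field * nucleus_mask

    cyto_mask = cell_mask & ~nucleus_mask
    rna = (
        params.baseline
        + params.w_spec * speckle_field * nucleus_mask
        + params.w_nuc * params.nucleoplasm_level * nucleus_mask
        + params.w_cyt * params.cyto_level * cyto_mask
    )

    nuc_spots = _sample_in_mask(
        nucleus_mask, rng, params.n_nuclear_spots, params.max_attempts,
        min_separation=params.spot_min_separation,
    )
    cyt_spots = _sample_in_mask(
        cyto_mask, rng, params.n_cyto_spots, params.max_attempts,
        min_separation=params.spot_min_separation, existing=nuc_spots,
    )
    all_spots = np.vstack([nuc_spots, cyt_spots]) if (len(nuc_spots) + len(cyt_spots)) else np.empty((0, 2), int)
    rna = rna + _gaussian_field(params.shape, all_spots, params.spot_sigma, params.spot_amp)

    if params.gain > 0:
        sc35 = rng.poisson(np.maximum(sc35, 0.0) * params.gain) / params.gain
        rna = rng.poisson(np.maximum(rna, 0.0) * params.gain) / params.gain

    truth = {
        "speckle_centers": speckle_centers,
        "nuclear_spots": nuc_spots,
        "cytoplasmic_spots": cyt_spots,
        "weights": (params.w_spec, params.w_nuc, params.w_cyt),
    }
    img = CellImage(
        sc35=sc35.astype(float),
        rna=rna.astype(float),
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        truth=truth,
    )
    img.validate()
    return img
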