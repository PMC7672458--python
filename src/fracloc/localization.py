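"""Per-gene localization-change statistics between knockdown and control.

The core statistic is a log2 ratio-of-ratios: for a contrast pair of
fractions (N, C) and a knockdown condition,

    delta_g = log2(N / C)_KD  -  log2(N / C)_control

computed from size-factor-normalized replicate means with a prior count,
with a delta-method standard error and an empirical-Bayes normal shrinkage
toward zero.  Positive delta means the gene's RNA became relatively more
nuclear after the knockdown.

The module also carries the expression filter (mean FPKM > 1, mitochondrial
genes excluded), median-of-ratios size factors, and the intronic read
fraction summary.  The estimator is exposed both as plain functions and as
a ``LocalizationModel`` / ``LocalizationResults`` pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simdata import FracSeqExperiment

__all__ = [
    "compute_fpkm",
    "filter_genes",
    "size_factors",
    "normalized_counts",
    "delta_localization",
    "intronic_read_fraction",
    "LocalizationModel",
    "LocalizationResults",
]

LN2 = math.log(2.0)

CONTRASTS = {
    "NC": ("nuclear", "cytoplasmic"),
    "NT": ("nuclear", "total"),
    "CT": ("cytoplasmic", "total"),
}


class NormalizationError(ValueError):
    pass


class DesignError(ValueError):
    pass


def compute_fpkm(
    counts: pd.DataFrame,
    exonic_lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = count / ((exonic_length/1e3) * (library_total/1e6)).

    ``totals`` defaults to the per-sample column sums of ``counts``.
    """
    lengths = exonic_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise NormalizationError(f"missing exonic length for genes {missing}")
    if (lengths <= 0).any():
        raise NormalizationError("exonic lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise NormalizationError("library totals must be positive")
    denom = np.outer(lengths.to_numpy(float) / 1e3, totals.to_numpy(float) / 1e6)
    return pd.DataFrame(counts.to_numpy(float) / denom, index=counts.index, columns=counts.columns)


def filter_genes(
    fpkm: pd.DataFrame,
    chromosomes: pd.Series,
    fpkm_min: float = 1.0,
    mito_label: str = "chrM",
) -> pd.Index:
    """Genes with mean FPKM (over all samples) strictly > fpkm_min, off chrM."""
    mean_fpkm = fpkm.mean(axis=1)
    chroms = chromosomes.reindex(fpkm.index)
    keep = (mean_fpkm > fpkm_min) & (chroms != mito_label)
    return fpkm.index[keep.fillna(False)]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    Reference is the per-gene geometric mean over samples, computed on genes
    with nonzero counts in every sample; each sample's factor is the median
    of its count/reference ratios over those genes.
    """
    x = counts.to_numpy(float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "no gene has nonzero counts in all samples; add a pseudocount before "
            "calling size_factors"
        )
    logx = np.log(x[all_pos])
    log_geo = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns)


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise NormalizationError("size factors must be positive and cover all samples")
    return counts / factors


def _cell_stats(
    norm: pd.DataFrame,
    exp: FracSeqExperiment,
    fraction: str,
    condition: str,
    prior_count: float,
    pool_variance: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and squared-CV (of the replicate mean, with prior) per gene."""
    samples = exp.samples(fraction=fraction, condition=condition)
    if not samples:
        raise DesignError(f"no samples for fraction={fraction!r}, condition={condition!r}")
    block = norm[samples].to_numpy(float)
    r = block.shape[1]
    mean = block.mean(axis=1)
    var = block.var(axis=1, ddof=1)
    ratio = var / (mean + prior_count) ** 2
    if pool_variance or r < 3:
        # with 2 replicates a per-gene variance is one-d.f.; pool the squared
        # CV across genes instead (median, robust to outliers)
        ratio = np.full_like(ratio, float(np.median(ratio)))
    return mean, ratio / r, r


def delta_localization(
    experiment: FracSeqExperiment,
    contrast: tuple[str, str] = ("nuclear", "cytoplasmic"),
    kd_condition: str = "KD_A",
    prior_count: float = 4.0,
    genes: pd.Index | Sequence[str] | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene delta = log2 ratio-of-ratios, its SE and shrunken estimate.

    ``delta_raw = log2((A+p)/(B+p))_KD - log2((A+p)/(B+p))_control`` on
    size-factor-normalized replicate means with prior count p.  The SE comes
    from delta-method propagation of the four replicate-mean variances
    (pooled across genes when only two replicates exist).  The shrunken
    estimate multiplies delta_raw by ``tau2 / (tau2 + se^2)`` with tau2 the
    method-of-moments prior variance across genes, floored at zero — it
    never changes sign and never increases magnitude.
    """
    experiment.validate()
    frac_a, frac_b = contrast
    conditions = set(experiment.design["condition"])
    for cond in ("control", kd_condition):
        if cond not in conditions:
            raise DesignError(f"condition {cond!r} missing from design")
    for frac in contrast:
        if frac not in set(experiment.design["fraction"]):
            raise DesignError(f"fraction {frac!r} missing from design")

    counts = experiment.counts
    if genes is not None:
        counts = counts.loc[list(genes)]
    if factors is None:
        factors = size_factors(experiment.counts)
    norm = normalized_counts(counts, factors)

    p = prior_count
    means, cv2 = {}, {}
    for cond in (kd_condition, "control"):
        for frac in contrast:
            m, v, _ = _cell_stats(norm, experiment, frac, cond, p, pool_variance=False)
            means[(frac, cond)] = m
            cv2[(frac, cond)] = v

    def log2_ratio(cond):
        return np.log2(means[(frac_a, cond)] + p) - np.log2(means[(frac_b, cond)] + p)

    delta_raw = log2_ratio(kd_condition) - log2_ratio("control")
    se2 = sum(cv2[key] for key in cv2) / LN2**2
    se = np.sqrt(se2)

    tau2 = max(0.0, float(np.var(delta_raw)) - float(np.mean(se2)))
    shrink = tau2 / (tau2 + se2) if tau2 > 0 else np.zeros_like(se2)
    delta_shrunk = delta_raw * shrink

    out = pd.DataFrame(
        {
            "delta_raw": delta_raw,
            "se": se,
            "delta_shrunk": delta_shrunk,
        },
        index=counts.index,
    )
    for (frac, cond), m in means.items():
        out[f"mean_{frac}_{cond}"] = m
    out.attrs["tau2"] = tau2
    out.attrs["contrast"] = contrast
    out.attrs["kd_condition"] = kd_condition
    out.attrs["prior_count"] = prior_count
    return out


def intronic_read_fraction(
    experiment: FracSeqExperiment,
    fraction: str,
    condition: str,
) -> pd.Series:
    """Per-sample fraction of reads assigned to introns, for one cell."""
    if experiment.intronic_counts is None:
        raise DesignError("experiment has no intronic count matrix")
    samples = experiment.samples(fraction=fraction, condition=condition)
    if not samples:
        raise DesignError(f"no samples for fraction={fraction!r}, condition={condition!r}")
    intr = experiment.intronic_counts[samples].sum(axis=0)
    exon = experiment.counts[samples].sum(axis=0)
    return intr / (intr + exon)


# ---------------------------------------------------------------------------
# Model / Results interface


class LocalizationModel:
    """Localization-change model over a fractionation experiment.

    Parameters
    ----------
    experiment : FracSeqExperiment
        Counts plus sample design.
    exonic_lengths : pd.Series, optional
        Per-gene median exonic lengths, required for the FPKM filter; if
        omitted the filter only excludes mitochondrial genes.
    chromosomes : pd.Series, optional
        Per-gene chromosome labels for the mitochondrial exclusion.
    prior_count : float
        Pseudocount added to normalized means before taking log ratios.
    fpkm_min : float
        Expression filter threshold (strict inequality on mean FPKM).
    """

    def __init__(
        self,
        experiment: FracSeqExperiment,
        exonic_lengths: pd.Series | None = None,
        chromosomes: pd.Series | None = None,
        prior_count: float = 4.0,
        fpkm_min: float = 1.0,
        mito_label: str = "chrM",
    ):
        experiment.validate()
        self.experiment = experiment
        self.prior_count = prior_count
        self.fpkm_min = fpkm_min
        self.mito_label = mito_label
        self.size_factors_ = size_factors(experiment.counts)

        genes = experiment.counts.index
        if chromosomes is None:
            chromosomes = pd.Series("unplaced", index=genes)
        if exonic_lengths is not None:
            fpkm = compute_fpkm(experiment.counts, exonic_lengths)
            self.retained_genes_ = filter_genes(fpkm, chromosomes, fpkm_min, mito_label)
        else:
            chroms = chromosomes.reindex(genes)
            self.retained_genes_ = genes[(chroms != mito_label).fillna(False)]

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        gene_metrics: pd.DataFrame | None = None,
        **kwargs,
    ) -> "LocalizationModel":
        """Build from a counts table and a sample design table.

        ``design`` needs columns fraction / condition / replicate indexed by
        sample; ``gene_metrics`` (as produced by
        :func:`fracloc.annotation.gene_metrics_table`) supplies exonic
        lengths and chromosomes for the filters.
        """
        exp = FracSeqExperiment(counts=counts, design=design)
        lengths = chroms = None
        if gene_metrics is not None:
            lengths = gene_metrics["exonic_length"]
            chroms = gene_metrics["chromosome"]
        return cls(exp, exonic_lengths=lengths, chromosomes=chroms, **kwargs)

    def fit(
        self,
        contrast: tuple[str, str] = ("nuclear", "cytoplasmic"),
        kd_condition: str = "KD_A",
    ) -> "LocalizationResults":
        table = delta_localization(
            self.experiment,
            contrast=contrast,
            kd_condition=kd_condition,
            prior_count=self.prior_count,
            genes=self.retained_genes_,
            factors=self.size_factors_,
        )
        return LocalizationResults(self, table)

    def fit_all(
        self,
        kd_conditions: Sequence[str] = ("KD_A", "KD_D"),
        contrasts: Sequence[tuple[str, str]] = tuple(CONTRASTS.values()),
    ) -> dict[tuple[str, str], "LocalizationResults"]:
        """Fit every (contrast, knockdown) combination present in the design."""
        out = {}
        for kd in kd_conditions:
            for contrast in contrasts:
                key = (f"{contrast[0][0].upper()}{contrast[1][0].upper()}", kd)
                out[key] = self.fit(contrast=contrast, kd_condition=kd)
        return out


@dataclass
class LocalizationResults:
    """Fitted localization-change table plus fit diagnostics."""

    model: LocalizationModel
    table: pd.DataFrame

    @property
    def contrast(self) -> tuple[str, str]:
        return self.table.attrs["contrast"]

    @property
    def kd_condition(self) -> str:
        return self.table.attrs["kd_condition"]

    @property
    def tau2(self) -> float:
        return self.table.attrs["tau2"]

    @property
    def delta(self) -> pd.Series:
        return self.table["delta_shrunk"]

    def summary(self) -> str:
        t = self.table
        a, b = self.contrast
        lines = [
            "Localization change results",
            "===========================",
            f"contrast:        log2({a}/{b})",
            f"knockdown:       {self.kd_condition} vs control",
            f"genes retained:  {len(t)}",
            f"prior count:     {t.attrs['prior_count']}",
            f"tau^2 (prior):   {self.tau2:.4f}",
            f"mean delta_raw:  {t['delta_raw'].mean():+.4f}",
            f"median delta:    {t['delta_shrunk'].median():+.4f}",
            f"delta IQR:       [{t['delta_shrunk'].quantile(0.25):+.4f}, "
            f"{t['delta_shrunk'].quantile(0.75):+.4f}]",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "kd_condition", self.kd_condition)
        out.insert(0, "contrast", f"{self.contrast[0]}/{self.contrast[1]}")
        out.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")
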