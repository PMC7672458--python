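"""Gene annotation model and architecture feature extraction.

The analyses in this package correlate how strongly a gene's RNA shifts
between nucleus and cytoplasm with the *architecture* of the gene: how long
the primary transcript (pre-mRNA) is, how many exons it has, how much of it
is intronic, and how long its 3'UTR is.  This module holds the in-memory
annotation model, a GENCODE-dialect GTF reader/writer, and the per-transcript
and gene-level-median feature calculations.

Coordinate convention: GTF files are 1-based with closed intervals; the
in-memory model is 0-based half-open (``length = end - start``).  Conversion
happens only at the file boundary.
"""

from __future__ import annotations

import math
import os
import statistics
from dataclasses import dataclass, field
from typing import Iterable

import gffutils

__all__ = [
    "Exon",
    "Transcript",
    "Gene",
    "AnnotationSet",
    "TranscriptMetrics",
    "GeneMetrics",
    "read_gtf",
    "write_gtf",
    "transcript_metrics",
    "gene_metrics",
    "assign_length_bin",
    "gene_metrics_table",
    "LENGTH_BIN_LABELS",
]

DEFAULT_BIOTYPES = frozenset({"protein_coding", "lncRNA"})
#: GENCODE v19 spells lncRNA biotypes several ways; accept common aliases.
_LNCRNA_ALIASES = frozenset({"lncRNA", "lincRNA", "long_noncoding_RNA"})

MITO_CHROM = "chrM"


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Exon:
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self):
        if self.end <= self.start:
            raise AnnotationError(f"empty exon interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    transcript_id: str
    start: int
    end: int
    exons: list[Exon] = field(default_factory=list)
    cds: list[Exon] = field(default_factory=list)  # CDS intervals, stop-codon excluded

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for ex in self.exons:
            if prev_end is not None and ex.start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping/unsorted exons"
                )
            prev_end = ex.end
        if self.exons[0].start < self.start or self.exons[-1].end > self.end:
            raise AnnotationError(
                f"transcript {self.transcript_id} exons exceed transcript span"
            )


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass
class AnnotationSet:
    """Ordered collection of genes with their transcript/exon structure."""

    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# GTF I/O


def _norm_biotype(raw: str) -> str:
    return "lncRNA" if raw in _LNCRNA_ALIASES else raw


def read_gtf(path: str | os.PathLike, biotypes: Iterable[str] = DEFAULT_BIOTYPES) -> AnnotationSet:
    """Read a GENCODE-dialect GTF, keeping genes whose gene_type is in *biotypes*.

    Genes, transcripts, exons and CDS records are grouped hierarchically.  A
    transcript without exon records is a validation error; a line gffutils
    cannot parse raises :class:`AnnotationError` naming the file.
    """
    biotypes = {_norm_biotype(b) for b in biotypes}
    try:
        db = gffutils.create_db(
            os.fspath(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted exception types
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    genes: list[Gene] = []
    for gf in db.features_of_type("gene", order_by="start"):
        biotype = _norm_biotype(gf.attributes.get("gene_type", ["unknown"])[0])
        if biotype not in biotypes:
            continue
        gene = Gene(
            gene_id=gf.attributes["gene_id"][0],
            chrom=gf.seqid,
            strand=gf.strand,
            biotype=biotype,
        )
        for tf in db.children(gf, featuretype="transcript", order_by="start"):
            tx = Transcript(
                transcript_id=tf.attributes["transcript_id"][0],
                start=tf.start - 1,
                end=tf.end,
            )
            for ef in db.children(tf, featuretype="exon", order_by="start"):
                tx.exons.append(Exon(ef.start - 1, ef.end))
            for cf in db.children(tf, featuretype="CDS", order_by="start"):
                tx.cds.append(Exon(cf.start - 1, cf.end))
            tx.validate()
            gene.transcripts.append(tx)
        if not gene.transcripts:
            raise AnnotationError(f"gene {gene.gene_id} has no transcripts")
        genes.append(gene)
    # deterministic order: by chromosome then start then id
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return AnnotationSet(genes)


def _gtf_line(chrom, src, feature, start0, end0, strand, attrs) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
    return f"{chrom}\t{src}\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr_str}\n"


def write_gtf(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    """Write the annotation as GENCODE-dialect GTF (1-based closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##description: fracloc synthetic annotation\n")
        fh.write("##format: gtf\n")
        for g in annotation.genes:
            base = [("gene_id", g.gene_id), ("gene_type", g.biotype)]
            fh.write(_gtf_line(g.chrom, "fracloc", "gene", g.start, g.end, g.strand, base))
            for t in g.transcripts:
                tattrs = base + [("transcript_id", t.transcript_id)]
                fh.write(
                    _gtf_line(g.chrom, "fracloc", "transcript", t.start, t.end, g.strand, tattrs)
                )
                for ex in t.exons:
                    fh.write(_gtf_line(g.chrom, "fracloc", "exon", ex.start, ex.end, g.strand, tattrs))
                for c in t.cds:
                    fh.write(_gtf_line(g.chrom, "fracloc", "CDS", c.start, c.end, g.strand, tattrs))


# ---------------------------------------------------------------------------
# Per-transcript metrics


@dataclass(frozen=True)
class TranscriptMetrics:
    """Architecture features of one transcript.

    ``pre_mrna_length`` is the genomic span including introns;
    ``exonic_length`` the mature (exons-only) length; ``fraction_intronic``
    the intronic share of the span; ``exon_density`` exons per nt of mature
    transcript; ``utr3_length`` is None for transcripts without CDS records.
    """

    pre_mrna_length: int
    exonic_length: int
    n_exons: int
    fraction_intronic: float
    exon_density: float
    utr3_length: int | None


def transcript_metrics(transcript: Transcript, strand: str = "+") -> TranscriptMetrics:
    transcript.validate()
    pre = transcript.end - transcript.start
    exonic = sum(e.length for e in transcript.exons)
    n = len(transcript.exons)
    utr3: int | None = None
    if transcript.cds:
        if strand == "-":
            # 3' end is the genomic start side
            cds_lo = min(c.start for c in transcript.cds)
            utr3 = sum(
                max(0, min(e.end, cds_lo) - e.start) for e in transcript.exons
            )
        else:
            cds_hi = max(c.end for c in transcript.cds)
            utr3 = sum(
                max(0, e.end - max(e.start, cds_hi)) for e in transcript.exons
            )
    return TranscriptMetrics(
        pre_mrna_length=pre,
        exonic_length=exonic,
        n_exons=n,
        fraction_intronic=(pre - exonic) / pre,
        exon_density=n / exonic,
        utr3_length=utr3,
    )


# ---------------------------------------------------------------------------
# Gene-level medians


@dataclass(frozen=True)
class GeneMetrics:
    gene_id: str
    biotype: str
    chromosome: str
    gene_length: int
    pre_mrna_length: float
    exonic_length: float
    n_exons: float            # median, possibly half-integer
    fraction_intronic: float
    exon_density: float
    utr3_length: float | None
    exon_class: str           # "single" iff median n_exons == 1 exactly
    rounded_exon_count: int   # median rounded half away from zero


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def gene_metrics(gene: Gene) -> GeneMetrics:
    """Median of each transcript metric across the gene's transcripts.

    The single/multi exon class uses the unrounded median: a gene is
    ``single`` only when the median exon count is exactly one.  Transcripts
    lacking CDS records are skipped (not counted as zero) in the 3'UTR
    median.
    """
    if not gene.transcripts:
        raise AnnotationError(f"gene {gene.gene_id} has no transcripts")
    per_tx = [transcript_metrics(t, gene.strand) for t in gene.transcripts]
    med = lambda vals: statistics.median(vals)
    n_exons_med = med([m.n_exons for m in per_tx])
    utr3_vals = [m.utr3_length for m in per_tx if m.utr3_length is not None]
    return GeneMetrics(
        gene_id=gene.gene_id,
        biotype=gene.biotype,
        chromosome=gene.chrom,
        gene_length=gene.end - gene.start,
        pre_mrna_length=med([m.pre_mrna_length for m in per_tx]),
        exonic_length=med([m.exonic_length for m in per_tx]),
        n_exons=n_exons_med,
        fraction_intronic=med([m.fraction_intronic for m in per_tx]),
        exon_density=med([m.exon_density for m in per_tx]),
        utr3_length=med(utr3_vals) if utr3_vals else None,
        exon_class="single" if n_exons_med == 1 else "multi",
        rounded_exon_count=_round_half_away(n_exons_med),
    )


LENGTH_BIN_LABELS = ("<10 kb", "10-20 kb", "20-30 kb", "30-40 kb", "40-50 kb", ">50 kb")
_BIN_EDGES_NT = (10_000, 20_000, 30_000, 40_000, 50_000)


def assign_length_bin(pre_mrna_length: float) -> str:
    """Bin a median pre-mRNA length (nt) into the standard kb windows.

    Bins are left-closed/right-open on the kb boundaries: exactly 10,000 nt
    falls in "10-20 kb"; anything >= 50,000 nt is ">50 kb".
    """
    if not pre_mrna_length > 0:
        raise AnnotationError(f"non-positive pre-mRNA length {pre_mrna_length}")
    for edge, label in zip(_BIN_EDGES_NT, LENGTH_BIN_LABELS):
        if pre_mrna_length < edge:
            return label
    return LENGTH_BIN_LABELS[-1]


def gene_metrics_table(annotation: AnnotationSet):
    """Per-gene metrics as a pandas DataFrame indexed by gene_id."""
    import pandas as pd

    rows = []
    for g in annotation.genes:
        m = gene_metrics(g)
        rows.append(
            {
                "gene_id": m.gene_id,
                "biotype": m.biotype,
                "chromosome": m.chromosome,
                "gene_length": m.gene_length,
                "pre_mrna_length": m.pre_mrna_length,
                "exonic_length": m.exonic_length,
                "n_exons": m.n_exons,
                "fraction_intronic": m.fraction_intronic,
                "exon_density": m.exon_density,
                "utr3_length": m.utr3_length,
                "exon_class": m.exon_class,
                "rounded_exon_count": m.rounded_exon_count,
                "length_bin": assign_length_bin(m.pre_mrna_length),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("gene_id")
    return df
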