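"""Strand-aware positional classification of lncRNA loci against coding genes.

Each lncRNA locus falls into exactly one of six positional classes,
decided in precedence order (most specific relationship first):

1. ``exon_sense_overlapping``  — same strand, overlaps an exon
2. ``intron_sense_overlapping``— same strand, overlaps the gene body but no exon
3. ``natural_antisense``       — opposite strand, overlaps an exon
4. ``intronic_antisense``      — opposite strand, fully inside an intron
5. ``bidirectional``           — no overlap; head-to-head, TSS-to-TSS < 1 kb,
                                 divergent orientation
6. ``intergenic``              — none of the above

The functional subtype then follows: intergenic loci inside an annotated
enhancer region are ``enhancer_like``, other intergenic loci are
``lincRNA``, the two antisense classes are ``antisense``, and
sense-overlapping or bidirectional loci are ``other``.

Coordinates are 0-based half-open internally; GTF input (1-based inclusive)
is converted on ingest. Transcript models are collapsed to one merged exon
set per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import gffutils
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


class PositionalClass(str, Enum):
    EXON_SENSE_OVERLAPPING = "exon_sense_overlapping"
    INTRON_SENSE_OVERLAPPING = "intron_sense_overlapping"
    NATURAL_ANTISENSE = "natural_antisense"
    INTRONIC_ANTISENSE = "intronic_antisense"
    BIDIRECTIONAL = "bidirectional"
    INTERGENIC = "intergenic"


ANTISENSE_CLASSES = {
    PositionalClass.NATURAL_ANTISENSE,
    PositionalClass.INTRONIC_ANTISENSE,
}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.name}: {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start position (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A coding gene with merged, non-overlapping exons."""

    gene_id: str
    symbol: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = _merge_exons(self.exons)
        for e in self.exons:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"exon outside gene body for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.interval.tss


def _merge_exons(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    if not exons:
        return []
    exons = sorted(exons, key=lambda e: (e.start, e.end))
    merged = [exons[0]]
    for e in exons[1:]:
        last = merged[-1]
        if e.start <= last.end:
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, e.end), last.strand, last.name
            )
        else:
            merged.append(e)
    return merged


class GeneIndex:
    """Per-chromosome interval index over gene models.

    Duplicate gene ids are collapsed (first occurrence wins), so
    classification is invariant to gene duplication in the input.
    """

    def __init__(self, genes: list[GeneModel]):
        seen: dict[str, GeneModel] = {}
        for g in genes:
            seen.setdefault(g.gene_id, g)
        self.genes = list(seen.values())
        self._trees: dict[str, IntervalTree] = {}
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            iv = g.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, g)
            self._by_chrom.setdefault(iv.chrom, []).append(g)

    def overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        return sorted(hits, key=lambda g: (g.interval.start, g.gene_id))

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])


def classify_locus(
    lnc: GenomicInterval,
    genes: GeneIndex,
    bidirectional_window: int = 1000,
) -> tuple[PositionalClass, list[str]]:
    """Assign one positional class and the partner genes triggering it."""
    if lnc.chrom not in genes._trees:
        log.warning("lncRNA %s on chromosome %s with no genes; intergenic",
                    lnc.name, lnc.chrom)
        return PositionalClass.INTERGENIC, []

    hits = genes.overlapping(lnc)
    buckets: dict[PositionalClass, list[str]] = {c: [] for c in PositionalClass}
    for g in hits:
        same = g.interval.strand == lnc.strand
        exon_overlap = any(lnc.overlaps(e) for e in g.exons)
        inside = g.interval.start <= lnc.start and lnc.end <= g.interval.end
        if same and exon_overlap:
            buckets[PositionalClass.EXON_SENSE_OVERLAPPING].append(g.gene_id)
        elif same:
            buckets[PositionalClass.INTRON_SENSE_OVERLAPPING].append(g.gene_id)
        elif exon_overlap:
            buckets[PositionalClass.NATURAL_ANTISENSE].append(g.gene_id)
        elif inside:
            buckets[PositionalClass.INTRONIC_ANTISENSE].append(g.gene_id)
        # opposite-strand body overlap neither on an exon nor fully intronic
        # matches no rule and falls through to the no-overlap classes below
    for cls in (
        PositionalClass.EXON_SENSE_OVERLAPPING,
        PositionalClass.INTRON_SENSE_OVERLAPPING,
        PositionalClass.NATURAL_ANTISENSE,
        PositionalClass.INTRONIC_ANTISENSE,
    ):
        if buckets[cls]:
            return cls, sorted(set(buckets[cls]))

    if not hits:
        partners = []
        for g in genes.on_chrom(lnc.chrom):
            if _is_divergent_pair(lnc, g, bidirectional_window):
                partners.append(g.gene_id)
        if partners:
            return PositionalClass.BIDIRECTIONAL, sorted(set(partners))
    return PositionalClass.INTERGENIC, []


def _is_divergent_pair(lnc: GenomicInterval, g: GeneModel, window: int) -> bool:
    """Head-to-head: TSSs strictly closer than ``window`` bp, transcription
    pointing away from each other, and no overlap."""
    if g.interval.strand == lnc.strand or lnc.overlaps(g.interval):
        return False
    if abs(lnc.tss - g.tss) >= window:
        return False
    if g.interval.strand == "+":
        return lnc.strand == "-" and lnc.tss <= g.tss
    return lnc.strand == "+" and lnc.tss >= g.tss


def assign_subtype(
    positional_class: PositionalClass,
    lnc: GenomicInterval,
    enhancers: list[GenomicInterval] | None = None,
) -> str:
    """lincRNA / enhancer_like / antisense / other, from the positional class."""
    if positional_class in ANTISENSE_CLASSES:
        return "antisense"
    if positional_class is PositionalClass.INTERGENIC:
        for enh in enhancers or []:
            if lnc.overlaps(enh):
                return "enhancer_like"
        return "lincRNA"
    return "other"


def classify_all(
    loci: list[GenomicInterval],
    genes: GeneIndex,
    enhancers: list[GenomicInterval] | None = None,
    bidirectional_window: int = 1000,
) -> pd.DataFrame:
    """Classify every locus; one row per lncRNA (lnc_id, class, subtype, partners)."""
    rows = []
    for lnc in loci:
        cls, partners = classify_locus(lnc, genes, bidirectional_window)
        rows.append(
            {
                "lnc_id": lnc.name,
                "positional_class": cls.value,
                "subtype": assign_subtype(cls, lnc, enhancers),
                "partner_gene_ids": ",".join(partners),
            }
        )
    return pd.DataFrame(rows, columns=["lnc_id", "positional_class", "subtype",
                                       "partner_gene_ids"])


def class_composition(classifications: pd.DataFrame) -> dict[str, float]:
    """Fraction of loci per positional class; fractions sum to 1."""
    if len(classifications) == 0:
        raise ValueError("no classifications")
    counts = classifications["positional_class"].value_counts()
    total = counts.sum()
    return {cls: float(counts.get(cls, 0)) / total for cls in counts.index}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gtf_genes(path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GTF file.

    GTF is 1-based inclusive; converted to 0-based half-open here.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        symbol = (g.attributes.get("gene_name") or [g.id])[0]
        interval = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand, g.id)
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand, g.id)
            for e in db.children(g, featuretype="exon")
        ]
        genes.append(GeneModel(gene_id=g.id, symbol=symbol, interval=interval,
                               exons=exons))
    return genes


def read_bed6(path) -> list[GenomicInterval]:
    """Read a BED6 file (0-based half-open) into stranded intervals."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "name": str},
    )
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.name)
        for r in bed.itertuples()
    ]


def write_classification_tsv(classifications: pd.DataFrame, path) -> None:
    classifications.to_csv(path, sep="\t", index=False)
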