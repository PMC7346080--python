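import numpy as np
import pytest

from lncforge.annotation import (GeneIndex, GeneModel, GenomicInterval,
                                 PositionalClass, assign_subtype,
                                 class_composition, classify_all,
                                 classify_locus, read_bed6, read_gtf_genes)
from lncforge.simulate import (SimulationConfig, generate_annotation, write_bed6,
                               write_gtf)


def make_gene(start=10_000, end=20_000, strand="+", gene_id="G1",
              exon_spans=None):
    """3-exon gene; default exons at offsets 0-1k, 4-5k and 9-10k from start."""
    iv = GenomicInterval("chr1", start, end, strand, gene_id)
    if exon_spans is None:
        exon_spans = ((start, start + 1_000), (start + 4_000, start + 5_000),
                      (end - 1_000, end))
    exons = [GenomicInterval("chr1", s, e, strand, gene_id) for s, e in exon_spans]
    return GeneModel(gene_id=gene_id, symbol=gene_id, interval=iv, exons=exons)


@pytest.fixture()
def index():
    return GeneIndex([make_gene()])


def lnc(start, end, strand):
    return GenomicInterval("chr1", start, end, strand, "L1")


class TestClassifyLocus:
    @pytest.mark.parametrize(
        "start, end, strand, expected",
        [
            (10_500, 11_500, "+", PositionalClass.EXON_SENSE_OVERLAPPING),
            (12_000, 13_000, "+", PositionalClass.INTRON_SENSE_OVERLAPPING),
            (10_500, 11_500, "-", PositionalClass.NATURAL_ANTISENSE),
            (12_000, 13_000, "-", PositionalClass.INTRONIC_ANTISENSE),
            (40_000, 41_000, "+", PositionalClass.INTERGENIC),
        ],
    )
    def test_each_overlap_class(self, index, start, end, strand, expected):
        cls, partners = classify_locus(lnc(start, end, strand), index)
        assert cls is expected
        if expected is not PositionalClass.INTERGENIC:
            assert partners == ["G1"]

    def test_bidirectional_boundary_strict(self, index):
        # gene TSS at 10_000 (plus strand); divergent minus-strand lncRNA
        # with TSS = end - 1. 999 bp away -> bidirectional, 1000 -> intergenic.
        near = lnc(8_000, 10_000 - 999 + 1, "-")   # tss = 9_001, distance 999
        cls, partners = classify_locus(near, index)
        assert cls is PositionalClass.BIDIRECTIONAL and partners == ["G1"]
        at_window = lnc(8_000, 10_000 - 1000 + 1, "-")  # tss = 9_000, distance 1000
        cls, _ = classify_locus(at_window, index)
        assert cls is PositionalClass.INTERGENIC

    def test_bidirectional_requires_divergence(self, index):
        # same side, same strand as gene: head-to-tail, not head-to-head
        cls, _ = classify_locus(lnc(8_500, 9_500, "+"), index)
        assert cls is PositionalClass.INTERGENIC

    def test_precedence_sense_exon_over_antisense(self):
        # two genes: one sense exon overlap, one antisense exon overlap
        g1 = make_gene(gene_id="G1")
        g2 = make_gene(strand="-", gene_id="G2")
        idx = GeneIndex([g1, g2])
        cls, partners = classify_locus(lnc(10_500, 11_500, "+"), idx)
        assert cls is PositionalClass.EXON_SENSE_OVERLAPPING
        assert partners == ["G1"]

    def test_invariant_to_gene_duplication_and_exon_order(self):
        g = make_gene()
        shuffled = make_gene(exon_spans=((19_000, 20_000), (10_000, 11_000),
                                         (14_000, 15_000)))
        single = classify_locus(lnc(12_000, 13_000, "-"), GeneIndex([g]))
        doubled = classify_locus(lnc(12_000, 13_000, "-"),
                                 GeneIndex([g, g, shuffled]))
        assert single == doubled

    def test_unknown_chromosome_intergenic(self, index):
        stray = GenomicInterval("chrUn", 100, 200, "+", "L1")
        cls, partners = classify_locus(stray, index)
        assert cls is PositionalClass.INTERGENIC and partners == []


class TestSubtype:
    def test_intergenic_in_enhancer(self):
        enh = [GenomicInterval("chr1", 39_000, 42_000, "+", "E1")]
        assert assign_subtype(PositionalClass.INTERGENIC,
                              lnc(40_000, 41_000, "+"), enh) == "enhancer_like"

    def test_intergenic_without_enhancer(self):
        assert assign_subtype(PositionalClass.INTERGENIC,
                              lnc(40_000, 41_000, "+"), []) == "lincRNA"

    def test_antisense_regardless_of_enhancer(self):
        enh = [GenomicInterval("chr1", 10_000, 12_000, "+", "E1")]
        assert assign_subtype(PositionalClass.NATURAL_ANTISENSE,
                              lnc(10_500, 11_500, "-"), enh) == "antisense"

    def test_bidirectional_is_other(self):
        assert assign_subtype(PositionalClass.BIDIRECTIONAL,
                              lnc(8_500, 9_500, "-"), []) == "other"


class TestComposition:
    def test_all_intergenic(self):
        table = classify_all([lnc(40_000, 41_000, "+")], GeneIndex([make_gene()]))
        assert class_composition(table) == {"intergenic": 1.0}

    def test_fractions_sum_to_one(self, bundle):
        truth = bundle["truth"]
        genes = read_gtf_genes(bundle["dir"] / "genes.gtf")
        loci = read_bed6(bundle["dir"] / "lnc_loci.bed")
        table = classify_all(loci, GeneIndex(genes))
        comp = class_composition(table)
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            class_composition(pd.DataFrame(columns=["positional_class"]))


class TestRoundTrip:
    def test_planted_classes_fully_recovered(self, tmp_path):
        config = SimulationConfig(seed=11)
        genes, loci, enhancers, gt = generate_annotation(config)
        # through files: GTF (1-based) and BED (0-based) round-trip included
        write_gtf(genes, tmp_path / "g.gtf")
        write_bed6(loci, tmp_path / "l.bed")
        write_bed6(enhancers, tmp_path / "e.bed")
        index = GeneIndex(read_gtf_genes(tmp_path / "g.gtf"))
        table = classify_all(read_bed6(tmp_path / "l.bed"), index,
                             read_bed6(tmp_path / "e.bed"))
        assert len(table) == sum(config.class_counts.values())
        for row in table.itertuples():
            assert gt.class_of[row.lnc_id] == row.positional_class
            assert gt.subtype_of[row.lnc_id] == row.subtype

    def test_empty_class_counts(self):
        config = SimulationConfig(seed=1, class_counts={}, n_enhancer_like=0)
        genes, loci, enhancers, gt = generate_annotation(config)
        assert loci == [] and len(genes) == 1

    def test_chromosome_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_annotation(SimulationConfig(seed=1, chrom_length=100_000))
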