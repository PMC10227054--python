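import numpy as np
import pytest

from scisokit.annotation import (
    Annotation,
    GeneModel,
    GenomicInterval,
    GtfParseError,
    TranscriptModel,
    exons_from_chain,
    junction_chain,
    read_annotation,
    site_catalog,
    write_annotation,
)


def make_transcript(tid, gene, strand, pairs, chrom="chr1"):
    return TranscriptModel(tid, gene, strand,
                           [GenomicInterval(chrom, s, e, strand) for s, e in pairs])


class TestGtfIO:
    def test_coordinate_convention(self, tmp_path):
        """GTF 1-based inclusive 1..100 / 201..300 becomes [(0,100),(200,300)]."""
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\texon\t201\t300\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        ann = read_annotation(gtf)
        t = ann.genes["G"].transcripts[0]
        assert [(e.start, e.end) for e in t.exons] == [(0, 100), (200, 300)]

    def test_round_trip_identity(self, tmp_path, synthetic_annotation):
        _, annotation, _, _ = synthetic_annotation
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_annotation(annotation, p1)
        again = read_annotation(p1)
        assert again == annotation
        write_annotation(again, p2)
        assert p1.read_text() == p2.read_text()

    def test_missing_transcript_id_names_line(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\texon\t201\t300\t.\t+\t.\tgene_id "G";\n'
        )
        with pytest.raises(GtfParseError, match="line 2"):
            read_annotation(gtf)

    def test_overlapping_exons_rejected_and_logged(self, tmp_path, caplog):
        gtf = tmp_path / "ov.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T1";\n'
            'chr1\tx\texon\t50\t150\t.\t+\t.\tgene_id "G"; transcript_id "T1";\n'
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T2";\n'
        )
        with caplog.at_level("WARNING"):
            ann = read_annotation(gtf)
        assert [t.transcript_id for t in ann.genes["G"].transcripts] == ["T2"]
        assert "T1" in caplog.text


class TestJunctionChain:
    def test_three_exons_two_junctions(self):
        t = make_transcript("T", "G", "+", [(0, 100), (200, 300), (400, 500)])
        assert junction_chain(t).junctions == ((100, 200), (300, 400))

    def test_mono_exon_empty(self):
        t = make_transcript("T", "G", "+", [(0, 500)])
        chain = junction_chain(t)
        assert chain.junctions == () and chain.is_mono_exonic

    def test_chain_exon_reconstruction_inverse(self, synthetic_annotation):
        """Rebuilding exons from (span, chain) recovers the exon list for 100+
        random synthetic transcripts."""
        _, annotation, novels, _ = synthetic_annotation
        ts = (list(annotation.transcripts()) + novels)[:150]
        assert len(ts) >= 100
        for t in ts:
            chain = junction_chain(t)
            rebuilt = exons_from_chain(t.chrom, t.start, t.end, chain.junctions, t.strand)
            assert rebuilt == t.exons


class TestSiteCatalog:
    def test_single_transcript(self):
        t = make_transcript("T", "G", "+", [(0, 100), (200, 300), (400, 500)])
        cat = site_catalog(GeneModel("G", "+", [t]))
        assert cat.donors == {100, 300}
        assert cat.acceptors == {200, 400}
        assert cat.junctions == {(100, 200), (300, 400)}

    def test_union_law_and_monotonicity(self):
        t1 = make_transcript("T1", "G", "+", [(0, 100), (200, 300), (400, 500)])
        t2 = make_transcript("T2", "G", "+", [(0, 100), (400, 500)])
        c1 = site_catalog(GeneModel("G", "+", [t1]))
        c12 = site_catalog(GeneModel("G", "+", [t1, t2]))
        assert c12.donors == c1.donors  # T2 reuses donor 100
        assert c12.junctions == c1.junctions | {(100, 400)}
        assert c1.donors <= c12.donors and c1.acceptors <= c12.acceptors

    def test_minus_strand_labels_swap(self):
        """On the minus strand the biological donor of each junction is the
        genomic-right coordinate (brute-force relabeling check)."""
        pairs = [(0, 100), (200, 300), (400, 500)]
        plus = site_catalog(GeneModel("G", "+", [make_transcript("T", "G", "+", pairs)]))
        minus = site_catalog(GeneModel("G", "-", [make_transcript("T", "G", "-", pairs)]))
        assert minus.donors == plus.acceptors
        assert minus.acceptors == plus.donors
        assert minus.junctions == plus.junctions


class TestInvariants:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_random_inverse_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 8))
            bounds = np.cumsum(rng.integers(20, 200, 2 * n))
            pairs = list(zip(bounds[::2], bounds[1::2]))
            strand = "+" if rng.random() < 0.5 else "-"
            t = make_transcript("T", "G", strand, pairs)
            chain = junction_chain(t)
            assert exons_from_chain(t.chrom, t.start, t.end,
                                    chain.junctions, strand) == t.exons

    def test_annotation_overlap_query(self):
        t = make_transcript("T", "G", "+", [(100, 200), (300, 400)])
        ann = Annotation([GeneModel("G", "+", [t])])
        assert [g.gene_id for g in ann.overlapping_genes("chr1", 150, 160)] == ["G"]
        assert ann.overlapping_genes("chr1", 500, 600) == []
        assert ann.overlapping_genes("chr1", 150, 160, strand="-") == []
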