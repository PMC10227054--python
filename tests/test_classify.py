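import numpy as np
import pytest

from scisokit.annotation import (
    Annotation,
    GeneModel,
    Genome,
    GenomicInterval,
    TranscriptModel,
    junction_chain,
    revcomp,
)
from scisokit.classify import (
    Peak,
    classify,
    end_support_filter,
    junction_artifact_check,
)

from .oracles import oracle_classify, random_structural_queries


def make_transcript(tid, gene, strand, pairs, chrom="chr1"):
    return TranscriptModel(tid, gene, strand,
                           [GenomicInterval(chrom, s, e, strand) for s, e in pairs])


@pytest.fixture()
def toy_annotation():
    t1 = make_transcript("T1", "G1", "+", [(50, 100), (200, 300), (400, 500)])
    t2 = make_transcript("T2", "G1", "+", [(50, 120), (400, 500)])
    t3 = make_transcript("T3", "G2", "-", [(1000, 1100), (1200, 1300)])
    return Annotation([GeneModel("G1", "+", [t1, t2]), GeneModel("G2", "-", [t3])])


class TestClassify:
    def test_fsm(self, toy_annotation):
        call = classify("chr1", "+", 50, 500, ((100, 200), (300, 400)), toy_annotation)
        assert call.category == "FSM" and call.ref_transcript_id == "T1"

    def test_ism_consecutive_suffix(self, toy_annotation):
        call = classify("chr1", "+", 210, 500, ((300, 400),), toy_annotation)
        assert call.category == "ISM" and call.ref_transcript_id == "T1"

    def test_nic_novel_combination(self, toy_annotation):
        # donor 100 and acceptor 400 are annotated, but the junction (100, 400)
        # itself is not: a novel combination of known sites
        call = classify("chr1", "+", 50, 500, ((100, 400),), toy_annotation)
        assert call.category == "NIC" and call.gene_id == "G1"

    def test_nnc_novel_site(self, toy_annotation):
        call = classify("chr1", "+", 50, 500, ((100, 200), (310, 400)), toy_annotation)
        assert call.category == "NNC"
        assert 310 in call.novel_donors

    def test_antisense(self, toy_annotation):
        call = classify("chr1", "-", 50, 500, ((100, 200),), toy_annotation)
        assert call.category == "antisense"

    def test_genic_intron_and_intergenic(self, toy_annotation):
        assert classify("chr1", "+", 130, 190, (), toy_annotation).category == "genic_intron"
        assert classify("chr1", "+", 5000, 5100, (), toy_annotation).category == "intergenic"
        assert classify("chrUn", "+", 0, 100, (), toy_annotation).category == "intergenic"

    def test_mono_exon_ism_inside_reference_exon(self, toy_annotation):
        call = classify("chr1", "+", 210, 290, (), toy_annotation)
        assert call.category == "ISM"

    def test_category_partition(self, noisefree_world):
        """Every isoform receives exactly one category; counts sum to total."""
        _, res = noisefree_world
        counts = res.report["isoforms"]["category_counts"]
        assert sum(counts.values()) == res.report["isoforms"]["total"]


class TestOracleEquivalence:
    def test_500_randomized_queries(self, synthetic_annotation):
        """Production classifier agrees with the brute-force chain/site oracle
        on 500 randomized queries over a 50-gene synthetic annotation."""
        _, annotation, _, _ = synthetic_annotation
        rng = np.random.default_rng(12)
        for q in random_structural_queries(annotation, rng, n=500):
            got = classify(*q[:4], q[4], annotation).category
            want = oracle_classify(*q[:4], q[4], annotation)
            assert got == want, q

    def test_strand_symmetry(self, toy_annotation):
        """Mirroring genome coordinates and flipping strands preserves the
        category of every query."""
        L = 10_000
        mirrored_genes = []
        for g in toy_annotation.genes.values():
            ts = []
            for t in g.transcripts:
                exons = [GenomicInterval(t.chrom, L - e.end, L - e.start,
                                         "-" if t.strand == "+" else "+")
                         for e in t.exons]
                ts.append(TranscriptModel(t.transcript_id, g.gene_id,
                                          exons[0].strand, exons))
            mirrored_genes.append(GeneModel(g.gene_id, ts[0].strand, ts))
        mirrored = Annotation(mirrored_genes)
        queries = [
            ("chr1", "+", 50, 500, ((100, 200), (300, 400))),
            ("chr1", "+", 210, 500, ((300, 400),)),
            ("chr1", "+", 50, 500, ((100, 200), (310, 400))),
            ("chr1", "-", 50, 500, ((100, 200),)),
            ("chr1", "+", 130, 190, ()),
        ]
        for chrom, strand, start, end, chain in queries:
            direct = classify(chrom, strand, start, end, chain, toy_annotation)
            m_strand = "-" if strand == "+" else "+"
            m_chain = tuple(sorted((L - r, L - l) for l, r in chain))
            mirror = classify(chrom, m_strand, L - end, L - start, m_chain, mirrored)
            assert direct.category == mirror.category


class TestJunctionArtifacts:
    def _genome(self, seq):
        return Genome({"chr1": seq})

    def test_canonical_unflagged_noncanonical_flagged(self):
        rng = np.random.default_rng(5)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        good = base[:100] + "GT" + base[102:198] + "AG" + base[200:]
        nc, rt = junction_artifact_check("chr1", "+", ((100, 200),), self._genome(good))
        assert not nc
        bad = base[:100] + "CT" + base[102:198] + "AC" + base[200:]
        nc, _ = junction_artifact_check("chr1", "+", ((100, 200),), self._genome(bad))
        assert nc
        # the same CT..AC intron is canonical on the minus strand
        nc, _ = junction_artifact_check("chr1", "-", ((100, 200),), self._genome(bad))
        assert not nc

    @pytest.mark.parametrize("replen,expected", [(8, True), (7, False)])
    def test_rt_switch_direct_repeat_at_k_boundary(self, replen, expected):
        """An 8-nt direct repeat straddling donor and acceptor flags RT
        switching; a 7-nt repeat does not (k = 8)."""
        rng = np.random.default_rng(6)
        base = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)]))
        base[100:102] = "GT"
        base[198:200] = "AG"
        # the repeat ends at each boundary; its tail coincides with the AG motif
        rep = "ACGTCAAG"[-replen:]
        base[100 - replen : 100] = rep  # exonic side of the donor
        base[200 - replen : 200] = rep  # intronic boundary of the acceptor
        # ensure positions just before the repeats differ so only `replen` matches
        base[100 - replen - 1] = "A"
        base[200 - replen - 1] = "C"
        genome = self._genome("".join(base))
        _, rt = junction_artifact_check("chr1", "+", ((100, 200),), genome, repeat_k=8)
        assert rt is expected

    def test_annotated_junctions_skipped(self):
        genome = self._genome("A" * 400)
        nc, rt = junction_artifact_check("chr1", "+", ((100, 200),), genome,
                                         annotated_junctions=frozenset({(100, 200)}))
        assert not nc and not rt

    def test_junction_off_contig_raises(self):
        with pytest.raises(ValueError, match="junction"):
            junction_artifact_check("chr1", "+", ((100, 600),), self._genome("A" * 400))


class TestEndSupportFilter:
    CAGE = [Peak("chr1", 1000, 1011, "+")]
    POLYA = [Peak("chr1", 5000, 5011, "+")]

    def _flags(self, start, end, category="NIC"):
        return end_support_filter(category, "chr1", "+", start, end,
                                  self.CAGE, self.POLYA)

    def test_boundary_inclusive_at_50(self):
        """A TSS exactly 50 nt from the last covered peak base (1010) is
        supported; 51 nt is not."""
        assert self._flags(1010 + 50, 5005).cage_supported
        assert not self._flags(1010 + 51, 5005).cage_supported
        assert self._flags(950, 5005).cage_supported  # 50 nt upstream of peak start

    def test_inside_peak_distance_zero(self):
        assert self._flags(1005, 5005).retained

    def test_fsm_exempt_from_filter(self):
        flags = end_support_filter("FSM", "chr1", "+", 0, 10, [], [])
        assert flags.retained and not flags.cage_supported

    def test_artifact_flags_block_retention(self):
        flags = end_support_filter("NIC", "chr1", "+", 1005, 5005,
                                   self.CAGE, self.POLYA, rt_switch=True)
        assert not flags.retained

    def test_minus_strand_ends(self):
        cage = [Peak("chr1", 5000, 5011, "-")]
        polya = [Peak("chr1", 1000, 1011, "-")]
        flags = end_support_filter("NIC", "chr1", "-", 1005, 5006, cage, polya)
        assert flags.cage_supported and flags.polya_supported and flags.retained

    def test_truth_isoforms_all_retained(self, noisefree_world):
        """With peaks placed at true ends, every expressed truth isoform
        passes the end-support filter."""
        _, res = noisefree_world
        assert res.report["isoforms"]["retained"] == res.report["isoforms"]["total"]
        assert all(i.retained for i in res.all_isoforms)
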