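import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scisokit.annotation import revcomp
from scisokit.demux import (
    PRIMER_3P,
    PRIMER_5P,
    FlncRecord,
    Rejection,
    correct_barcode,
    dedup_umis,
    demux_reads,
    extract_flnc,
)

WL = ["ACGTACGTACGTACGT", "TTTTCCCCGGGGAAAA", "ACGTACGTACGTACGA"]
BC = WL[0]
UMI = "AACCGGTTAACC"


def build_read(insert="TGCATGCATGCATGCATGC", polya=30, umi=UMI, bc=BC):
    return PRIMER_5P + insert + "A" * polya + umi + bc + PRIMER_3P


class TestExtractFlnc:
    def test_exact_read_recovered(self):
        rec = extract_flnc("r1", build_read(), WL)
        assert isinstance(rec, FlncRecord)
        assert rec.barcode == BC and rec.umi == UMI
        assert rec.insert == "TGCATGCATGCATGCATGC"
        assert rec.polya_len == 30
        assert rec.orientation == "as-sequenced"

    def test_reverse_complement_symmetry(self):
        fwd = extract_flnc("r1", build_read(), WL)
        rev = extract_flnc("r1", revcomp(build_read()), WL)
        assert isinstance(rev, FlncRecord)
        assert rev.orientation == "reverse-complemented"
        assert (rev.barcode, rev.umi, rev.insert, rev.polya_len) == \
            (fwd.barcode, fwd.umi, fwd.insert, fwd.polya_len)

    @pytest.mark.parametrize("polya,ok", [(20, True), (19, False)])
    def test_polya_minimum_boundary(self, polya, ok):
        """A polyA run of exactly 20 nt passes; 19 nt is rejected."""
        res = extract_flnc("r1", build_read(insert="TGCTGCTGC", polya=polya), WL)
        if ok:
            assert isinstance(res, FlncRecord) and res.polya_len == 20
        else:
            assert isinstance(res, Rejection) and res.reason == "no-polyA"

    def test_missing_primers(self):
        assert extract_flnc("r1", "ACGT" * 30, WL).reason == "no-5'-primer"
        no3 = PRIMER_5P + "TGC" * 20 + "A" * 30 + UMI + BC + "ACGTACGTACGTACGTACGT"
        assert extract_flnc("r1", no3, WL).reason == "no-3'-primer"
        assert extract_flnc("r1", "", WL).reason == "no-5'-primer"

    def test_unmatched_barcode_rejected(self):
        res = extract_flnc("r1", build_read(bc="G" * 16), WL)
        assert isinstance(res, Rejection) and res.reason == "barcode-unmatched"


class TestCorrectBarcode:
    def test_exact_identity(self):
        assert correct_barcode(BC, WL) == (BC, None)

    def test_unique_hamming1_corrected(self):
        """Any single substitution of an isolated whitelist entry is recovered
        (checked against an exhaustive Hamming scan)."""
        target = WL[1]
        for pos in range(16):
            for alt in "ACGT":
                if alt == target[pos]:
                    continue
                observed = target[:pos] + alt + target[pos + 1 :]
                dists = sorted(sum(a != b for a, b in zip(observed, w)) for w in WL)
                expected = (target, None) if dists[1] > 1 else (None, "ambiguous")
                assert correct_barcode(observed, WL) == expected

    def test_ambiguous_discarded(self):
        # WL[0] and WL[2] differ at the last base only: their midpoint is ambiguous
        observed = "ACGTACGTACGTACGC"
        assert correct_barcode(observed, WL) == (None, "ambiguous")

    def test_wrong_length_unmatched(self):
        assert correct_barcode("ACGT", WL) == (None, "unmatched")

    def test_empty_whitelist_raises(self):
        with pytest.raises(ValueError):
            correct_barcode(BC, [])


class TestDedupUmis:
    def _rec(self, rid, bc=BC, umi=UMI, insert="TGCA" * 5):
        return FlncRecord(rid, bc, umi, "as-sequenced", insert, 30)

    def test_identical_triples_collapse(self):
        recs = [self._rec(f"r{i}") for i in range(3)]
        chains = {r.read_id: ("chr1", "+", ((10, 20),)) for r in recs}
        out = dedup_umis(recs, chains)
        assert len(out) == 1 and out[0].read_id == "r0"

    def test_different_chains_kept(self):
        recs = [self._rec("r0"), self._rec("r1")]
        chains = {"r0": ("chr1", "+", ((10, 20),)), "r1": ("chr1", "+", ((10, 30),))}
        assert len(dedup_umis(recs, chains)) == 2

    def test_longest_insert_survives(self):
        recs = [self._rec("r1", insert="TG"), self._rec("r0", insert="TGCATGCA")]
        chains = {r.read_id: "k" for r in recs}
        assert dedup_umis(recs, chains)[0].read_id == "r0"

    def test_count_equals_distinct_triples(self, noisefree_world):
        """On a simulation with known PCR-duplicate structure, the
        deduplicated molecule count equals the brute-force number of distinct
        (barcode, UMI, junction chain) triples."""
        exp, res = noisefree_world
        truth = exp.manifest
        triples = set()
        for info in truth.reads.values():
            iso = truth.isoforms[info["isoform"]]
            triples.add((info["barcode"], info["umi"],
                         iso["chrom"], iso["strand"], tuple(map(tuple, iso["chain"]))))
        assert res.report["reads"]["deduplicated_molecules"] == len(triples)


class TestPartition:
    def test_every_read_flnc_or_rejected(self, noisy_world):
        exp, res = noisy_world
        r = res.report["reads"]
        assert r["flnc"] + sum(r["rejected_by_reason"].values()) == r["input"]
        assert r["input"] == len(exp.manifest.reads)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    insert=st.text(alphabet="ACGT", min_size=5, max_size=60),
    umi=st.text(alphabet="ACGT", min_size=12, max_size=12),
)
def test_orientation_invariance_property(insert, umi):
    """extract_flnc(rc(read)) equals extract_flnc(read) up to the flag."""
    read = PRIMER_5P + insert + "A" * 25 + umi + BC + PRIMER_3P
    a = extract_flnc("r", read, WL)
    b = extract_flnc("r", revcomp(read), WL)
    if isinstance(a, Rejection):
        assert isinstance(b, Rejection) and b.reason == a.reason
    else:
        assert (a.barcode, a.umi, a.insert, a.polya_len) == \
            (b.barcode, b.umi, b.insert, b.polya_len)
        assert {a.orientation, b.orientation} == {"as-sequenced", "reverse-complemented"}
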