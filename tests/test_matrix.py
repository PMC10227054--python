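import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scisokit.collapse import IsoformRecord
from scisokit.matrix import (
    CellMatrix,
    JunctionSupport,
    build_matrix,
    cross_platform_correlation,
    novel_per_gene_histogram,
    per_cluster_category_proportions,
    specificity_sets,
    validate_junctions,
)


def iso(iid, junctions, strand="+", chrom="chr1"):
    start = 0 if not junctions else max(0, junctions[0][0] - 100)
    end = (start + 500) if not junctions else junctions[-1][1] + 100
    return IsoformRecord(iid, chrom, strand, tuple(junctions), start, end, [])


class TestValidateJunctions:
    SUPPORT = JunctionSupport({
        ("chr1", 100, 200, "+"): 6,
        ("chr1", 300, 400, "+"): 5,
        ("chr1", 500, 600, "+"): 7,
    })

    def test_strict_greater_than_five(self):
        """6 unique reads validate a junction; 5 do not."""
        df = validate_junctions([iso("a", [(100, 200)]), iso("b", [(300, 400)])],
                                self.SUPPORT)
        assert df.loc["a", "validated"] == True  # noqa: E712
        assert df.loc["b", "validated"] == False  # noqa: E712

    def test_all_junctions_required(self):
        """{6,7} validates a two-junction isoform; {6,5} does not."""
        good = iso("good", [(100, 200), (500, 600)])
        bad = iso("bad", [(100, 200), (300, 400)])
        df = validate_junctions([good, bad], self.SUPPORT)
        assert df.loc["good", "validated"] == True  # noqa: E712
        assert df.loc["bad", "validated"] == False  # noqa: E712

    def test_mono_exon_na(self):
        df = validate_junctions([iso("m", [])], self.SUPPORT)
        assert df.loc["m", "validated"] is pd.NA

    def test_minus_strand_biological_lookup(self):
        support = JunctionSupport({("chr1", 200, 100, "-"): 9})
        df = validate_junctions([iso("m", [(100, 200)], strand="-")], support)
        assert df.loc["m", "validated"] == True  # noqa: E712

    def test_monotone_in_threshold(self):
        isos = [iso("a", [(100, 200)]), iso("b", [(300, 400)]),
                iso("c", [(500, 600)])]
        validated = [
            set(validate_junctions(isos, self.SUPPORT, min_unique=k)
                .query("validated == True").index)
            for k in (4, 5, 6, 7)
        ]
        for lo, hi in zip(validated[1:], validated):
            assert lo <= hi

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "sj.tsv"
        self.SUPPORT.to_tsv(p)
        assert JunctionSupport.from_tsv(p).counts == self.SUPPORT.counts

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            JunctionSupport({("chr1", 1, 2, "+"): -1})


class TestBuildMatrix:
    CLUSTERS = {"BC1": "IHC", "BC2": "IHC", "BC3": "OHC"}

    def test_distinct_umis_counted(self):
        cm = build_matrix([("i1", "BC1", "u1"), ("i1", "BC1", "u2"),
                           ("i1", "BC1", "u3")], self.CLUSTERS)
        assert cm.total() == 3
        assert cm.matrix[0, 0] == 3

    def test_duplicate_umis_collapse(self):
        cm = build_matrix([("i1", "BC1", "u1"), ("i1", "BC1", "u1")], self.CLUSTERS)
        assert cm.total() == 1

    def test_filtered_view_thresholds(self):
        """An isoform seen in 2 cells disappears from the filtered view
        (min_cells=3) but stays in the raw matrix."""
        assigns = [("i1", "BC1", "u1"), ("i1", "BC2", "u2"),
                   ("i2", "BC1", "u3"), ("i2", "BC2", "u4"), ("i2", "BC3", "u5")]
        cm = build_matrix(assigns, self.CLUSTERS)
        view = cm.filtered_view(min_cells=3, min_isoforms_per_cell=1)
        assert "i1" in cm.isoform_ids
        assert view.isoform_ids == ["i2"]

    def test_unknown_barcode_warns(self, caplog):
        with caplog.at_level("WARNING"):
            cm = build_matrix([("i1", "BCX", "u1")], self.CLUSTERS)
        assert cm.clusters["BCX"] == "unknown"
        assert "BCX" in caplog.text


class TestSpecificity:
    def _matrix(self):
        assigns = [("i1", "BC1", "u1"), ("i1", "BC2", "u2"),  # IHC only
                   ("i2", "BC1", "u3"), ("i2", "BC3", "u4"),  # IHC + OHC
                   ("i3", "BC3", "u5")]  # OHC only
        return build_matrix(assigns, {"BC1": "IHC", "BC2": "IHC", "BC3": "OHC"})

    def test_cluster_sets_and_upset_partition(self):
        spec = specificity_sets(self._matrix())
        assert spec.cluster_sets["i1"] == {"IHC"}
        assert spec.cluster_sets["i2"] == {"IHC", "OHC"}
        assert spec.cluster_sets["i3"] == {"OHC"}
        assert sum(spec.upset_tally.values()) == 3  # partition of the isoform set

    def test_detect_min_threshold(self):
        spec = specificity_sets(self._matrix(), detect_min=2)
        assert spec.cluster_sets["i1"] == {"IHC"}
        assert spec.cluster_sets["i2"] == frozenset()

    def test_category_proportions_sum_to_one(self):
        spec = specificity_sets(self._matrix())
        cats = {"i1": "FSM", "i2": "NIC", "i3": "NNC"}
        props = per_cluster_category_proportions(spec, cats)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_novel_per_gene_histogram(self):
        cats = {"i1": "FSM", "i2": "NIC", "i3": "NNC", "i4": "NNC"}
        genes = {"i1": "G1", "i2": "G1", "i3": "G1", "i4": "G2"}
        hist = novel_per_gene_histogram(cats, genes)
        assert hist.to_dict() == {"G1": 2, "G2": 1}


class TestCrossPlatform:
    def test_identical_matrices_correlate_perfectly(self):
        rng = np.random.default_rng(4)
        m = sp.csr_matrix(rng.integers(0, 5, (20, 6)))
        bcs = [f"BC{i}" for i in range(6)]
        cm = CellMatrix(m, [f"i{k}" for k in range(20)], bcs,
                        pd.Series(["C1"] * 6, index=bcs))
        out = cross_platform_correlation(cm, m, bcs)
        assert out["umi_r"] == pytest.approx(1.0)
        assert out["feature_r"] == pytest.approx(1.0)

    def test_too_few_shared_barcodes(self):
        m = sp.csr_matrix(np.ones((3, 2)))
        cm = CellMatrix(m, ["a", "b", "c"], ["BC1", "BC2"],
                        pd.Series(["C1", "C1"], index=["BC1", "BC2"]))
        with pytest.raises(ValueError):
            cross_platform_correlation(cm, m, ["BCX", "BCY"])
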