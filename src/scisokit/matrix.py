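"""Short-read junction validation, isoform-by-cell matrix, specificity sets.

Junction validation applies the strict short-read support rule: a junction is
validated when its unique-read count exceeds ``min_unique`` (default 5, i.e.
>=6 reads), and an isoform is validated only when every one of its junctions
is. The cell matrix counts deduplicated UMIs per (isoform, barcode); the
min-cells / min-features filter is an auxiliary view only and never touches
the catalog itself.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import Junction

logger = logging.getLogger(__name__)


class JunctionSupport:
    """Map (chrom, donor, acceptor, strand) -> unique short-read count.

    Donor/acceptor are biological (strand-aware) coordinates, matching the
    junction-count TSV convention.
    """

    def __init__(self, counts: Mapping[tuple[str, int, int, str], int]) -> None:
        for key, v in counts.items():
            if v < 0 or int(v) != v:
                raise ValueError(f"support count for {key} must be a non-negative integer")
        self.counts = {k: int(v) for k, v in counts.items()}

    @classmethod
    def from_tsv(cls, path) -> "JunctionSupport":
        df = pd.read_csv(path, sep="\t")
        return cls({
            (r.chrom, int(r.donor), int(r.acceptor), r.strand): int(r.unique_count)
            for r in df.itertuples()
        })

    def to_tsv(self, path) -> None:
        rows = [
            {"chrom": c, "donor": d, "acceptor": a, "strand": s, "unique_count": n}
            for (c, d, a, s), n in sorted(self.counts.items())
        ]
        pd.DataFrame(rows, columns=["chrom", "donor", "acceptor", "strand",
                                    "unique_count"]).to_csv(path, sep="\t", index=False)

    def get(self, chrom: str, donor: int, acceptor: int, strand: str) -> int:
        return self.counts.get((chrom, donor, acceptor, strand), 0)


def biological_junction(junction: Junction, strand: str) -> tuple[int, int]:
    """(donor, acceptor) coordinates of a genomic (left, right) junction."""
    left, right = junction
    return (left, right) if strand == "+" else (right, left)


def validate_junctions(
    isoforms: Sequence,
    support: JunctionSupport,
    min_unique: int = 5,
) -> pd.DataFrame:
    """Per-isoform junction validation against short-read unique counts.

    A junction validates iff count > ``min_unique`` (strict). Mono-exon
    isoforms have no junctions; their ``validated`` field is NA.
    """
    rows = []
    for iso in isoforms:
        if not iso.junctions:
            rows.append({"isoform_id": iso.isoform_id, "n_junctions": 0,
                         "n_validated": 0, "validated": pd.NA})
            continue
        ok = 0
        for j in iso.junctions:
            d, a = biological_junction(j, iso.strand)
            if support.get(iso.chrom, d, a, iso.strand) > min_unique:
                ok += 1
        rows.append({"isoform_id": iso.isoform_id, "n_junctions": len(iso.junctions),
                     "n_validated": ok, "validated": ok == len(iso.junctions)})
    return pd.DataFrame(rows).set_index("isoform_id")


@dataclass
class CellMatrix:
    """Sparse isoform-by-cell UMI count matrix with a barcode->cluster table."""

    matrix: sp.csr_matrix
    isoform_ids: list[str]
    barcodes: list[str]
    clusters: pd.Series  # index = barcodes

    def total(self) -> int:
        return int(self.matrix.sum())

    def filtered_view(self, min_cells: int = 3, min_isoforms_per_cell: int = 50) -> "CellMatrix":
        """Auxiliary filtered view: drop isoforms seen in < min_cells cells and
        cells with < min_isoforms_per_cell detected isoforms."""
        cells_per_iso = np.asarray((self.matrix > 0).sum(axis=1)).ravel()
        isos_per_cell = np.asarray((self.matrix > 0).sum(axis=0)).ravel()
        keep_r = cells_per_iso >= min_cells
        keep_c = isos_per_cell >= min_isoforms_per_cell
        sub = self.matrix[keep_r][:, keep_c].tocsr()
        bcs = [b for b, k in zip(self.barcodes, keep_c) if k]
        return CellMatrix(
            sub,
            [i for i, k in zip(self.isoform_ids, keep_r) if k],
            bcs,
            self.clusters.loc[bcs],
        )

    def to_mtx(self, prefix) -> None:
        import scipy.io

        scipy.io.mmwrite(f"{prefix}.mtx", sp.coo_matrix(self.matrix))
        pd.Series(self.isoform_ids).to_csv(f"{prefix}.rows.tsv", sep="\t",
                                           index=False, header=False)
        pd.Series(self.barcodes).to_csv(f"{prefix}.cols.tsv", sep="\t",
                                        index=False, header=False)


def build_matrix(
    assignments: Iterable[tuple[str, str, str]],
    barcode_clusters: Mapping[str, str],
) -> CellMatrix:
    """Build the isoform-by-cell matrix from deduplicated molecule assignments.

    ``assignments`` yields (isoform_id, barcode, umi) for deduplicated FLNC
    molecules; the count per (isoform, barcode) is the number of distinct
    UMIs. Barcodes missing from the cluster table go to an "unknown" cluster
    with a warning.
    """
    per_cell: dict[tuple[str, str], set[str]] = {}
    for iso, bc, umi in assignments:
        per_cell.setdefault((iso, bc), set()).add(umi)
    isoform_ids = sorted({iso for iso, _ in per_cell})
    barcodes = sorted({bc for _, bc in per_cell})
    row_index = {iso: i for i, iso in enumerate(isoform_ids)}
    col_index = {bc: i for i, bc in enumerate(barcodes)}
    rows, cols, vals = [], [], []
    for (iso, bc), umis in sorted(per_cell.items()):
        rows.append(row_index[iso])
        cols.append(col_index[bc])
        vals.append(len(umis))
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(isoform_ids), len(barcodes)), dtype=np.int64
    )
    labels = []
    for bc in barcodes:
        if bc not in barcode_clusters:
            logger.warning("barcode %s absent from cluster table; assigned 'unknown'", bc)
            labels.append("unknown")
        else:
            labels.append(barcode_clusters[bc])
    return CellMatrix(mat, isoform_ids, barcodes, pd.Series(labels, index=barcodes))


@dataclass
class SpecificityResult:
    cluster_sets: dict[str, frozenset[str]]  # isoform -> clusters detected in
    upset_tally: dict[frozenset[str], int]  # cluster-set -> number of isoforms
    detect_min: int


def specificity_sets(cm: CellMatrix, detect_min: int = 1) -> SpecificityResult:
    """Per-isoform detected-cluster sets and the UpSet intersection tally.

    An isoform is detected in a cluster when its summed count over that
    cluster's cells reaches ``detect_min``; it is cell-type-specific when
    detected in exactly one cluster. The tally partitions the isoform set.
    """
    cluster_names = sorted(cm.clusters.unique())
    masks = {
        cl: np.asarray(cm.clusters.values == cl) for cl in cluster_names
    }
    cluster_sets: dict[str, frozenset[str]] = {}
    tally: Counter = Counter()
    dense_ok = cm.matrix.shape[0] * cm.matrix.shape[1] < 5_000_000
    mat = cm.matrix.toarray() if dense_ok else cm.matrix
    for i, iso in enumerate(cm.isoform_ids):
        row = mat[i] if dense_ok else np.asarray(mat[i].todense()).ravel()
        detected = frozenset(
            cl for cl in cluster_names if int(row[masks[cl]].sum()) >= detect_min
        )
        cluster_sets[iso] = detected
        tally[detected] += 1
    return SpecificityResult(cluster_sets, dict(tally), detect_min)


def per_cluster_category_proportions(
    spec: SpecificityResult, categories: Mapping[str, str]
) -> pd.DataFrame:
    """Proportion of FSM/ISM/NIC/NNC among isoforms detected in each cluster."""
    cats = ("FSM", "ISM", "NIC", "NNC")
    rows: dict[str, Counter] = {}
    for iso, clusters in spec.cluster_sets.items():
        cat = categories.get(iso)
        if cat not in cats:
            continue
        for cl in clusters:
            rows.setdefault(cl, Counter())[cat] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cats).fillna(0)
    totals = out.sum(axis=1)
    return out.div(totals.replace(0, np.nan), axis=0).fillna(0.0).sort_index()


def novel_per_gene_histogram(
    categories: Mapping[str, str], gene_ids: Mapping[str, str | None]
) -> pd.Series:
    """Number of novel (NIC/NNC) isoforms per assigned gene."""
    counts: Counter = Counter()
    for iso, cat in categories.items():
        if cat in ("NIC", "NNC") and gene_ids.get(iso):
            counts[gene_ids[iso]] += 1
    return pd.Series(dict(counts), dtype=int).sort_index()


def cross_platform_correlation(
    long_cm: CellMatrix, short_matrix: sp.spmatrix, short_barcodes: Sequence[str]
) -> dict[str, float]:
    """Per-barcode Pearson correlations between platforms.

    Correlates, across barcodes shared by the two matrices, total UMI counts
    and detected feature counts. Returns {"umi_r": ..., "feature_r": ...}.
    """
    short_idx = {bc: i for i, bc in enumerate(short_barcodes)}
    shared = [bc for bc in long_cm.barcodes if bc in short_idx]
    if len(shared) < 2:
        raise ValueError("need >=2 shared barcodes for a correlation")
    long_col = {bc: i for i, bc in enumerate(long_cm.barcodes)}
    short_csc = sp.csc_matrix(short_matrix)
    long_csc = sp.csc_matrix(long_cm.matrix)
    lu, su, lf, sf = [], [], [], []
    for bc in shared:
        lcol = long_csc[:, long_col[bc]]
        scol = short_csc[:, short_idx[bc]]
        lu.append(lcol.sum())
        su.append(scol.sum())
        lf.append((lcol > 0).sum())
        sf.append((scol > 0).sum())
    def _pearson(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.std() == 0 or y.std() == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])
    return {"umi_r": _pearson(lu, su), "feature_r": _pearson(lf, sf)}
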