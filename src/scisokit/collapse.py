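"""Collapse spliced long-read alignments into unique isoforms.

Multi-exon reads merge on exact junction-chain identity; transcript ends never
distinguish multi-exon isoforms (incomplete-splice-match detection happens at
classification, not here). Mono-exon reads merge under reciprocal overlap with
end differences within ``end_fuzz``. Loci are connected components of genomic
overlap on one strand, numbered in genomic order, yielding PB-style
``PB.<locus>.<index>`` identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from .annotation import GenomicInterval, Junction, exons_from_chain


@dataclass(frozen=True)
class AlignedChain:
    read_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic (start, end), sorted
    mapq: int

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def junctions(self) -> tuple[Junction, ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    def chain_key(self) -> tuple:
        """Hashable key identifying the splicing structure (used for UMI dedup)."""
        if self.junctions:
            return (self.chrom, self.strand, self.junctions)
        # mono-exon reads: bin ends coarsely so 3' jitter does not split molecules
        return (self.chrom, self.strand, "mono", self.start // 100, self.end // 100)


@dataclass
class IsoformRecord:
    isoform_id: str
    chrom: str
    strand: str
    junctions: tuple[Junction, ...]
    start: int  # representative span: 5'-most start / 3'-most end among members
    end: int
    read_ids: list[str]
    cell_counts: dict[str, int] = field(default_factory=dict)
    # attached downstream
    category: str | None = None
    gene_id: str | None = None
    retained: bool | None = None

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def exons(self) -> list[GenomicInterval]:
        return exons_from_chain(self.chrom, self.start, self.end, self.junctions, self.strand)


_REF_CONSUME = set("MDN=X")
_QUERY_ONLY = set("IS")


def chain_from_alignment(
    rec: pysam.AlignedSegment, min_mapq: int = 20
) -> tuple[AlignedChain | None, str | None]:
    """Exon chain of one SAM record, or (None, reason).

    M/=/X/D advance the reference within the current exon; N closes an exon
    and opens the next. Reads below ``min_mapq`` or unmapped are rejected.
    """
    if rec.is_unmapped:
        return None, "unmapped"
    if rec.mapping_quality < min_mapq:
        return None, "low-mapq"
    pos = rec.reference_start
    exon_start = pos
    exons: list[tuple[int, int]] = []
    for op, length in rec.cigartuples:
        code = "MIDNSHP=XB"[op]
        if code in _REF_CONSUME and code != "N":
            pos += length
        elif code == "N":
            exons.append((exon_start, pos))
            pos += length
            exon_start = pos
        elif code in _QUERY_ONLY or code in "HP":
            continue
        else:
            raise ValueError(f"read {rec.query_name}: unsupported CIGAR opcode {code!r}")
    exons.append((exon_start, pos))
    strand = "-" if rec.is_reverse else "+"
    return AlignedChain(rec.query_name, rec.reference_name, strand, tuple(exons),
                        rec.mapping_quality), None


def read_sam(path, min_mapq: int = 20):
    """Parse a SAM/BAM file into accepted chains plus a rejection tally."""
    chains: list[AlignedChain] = []
    rejected: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            chain, reason = chain_from_alignment(rec, min_mapq=min_mapq)
            if chain is None:
                rejected[reason] = rejected.get(reason, 0) + 1
            else:
                chains.append(chain)
    return chains, rejected


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _merge_mono_exon(chains: Sequence[AlignedChain], end_fuzz: int):
    """Cluster mono-exon chains: reciprocal overlap with both end diffs <= fuzz."""
    order = sorted(range(len(chains)), key=lambda i: (chains[i].start, chains[i].end))
    uf = _UnionFind(len(chains))
    for ii, i in enumerate(order):
        ci = chains[i]
        for j in order[ii + 1 :]:
            cj = chains[j]
            if cj.start - ci.start > end_fuzz:
                break
            if abs(ci.start - cj.start) <= end_fuzz and abs(ci.end - cj.end) <= end_fuzz \
                    and ci.start < cj.end and cj.start < ci.end:
                uf.union(i, j)
    groups: dict[int, list[AlignedChain]] = {}
    for i, c in enumerate(chains):
        groups.setdefault(uf.find(i), []).append(c)
    return list(groups.values())


def collapse_chains(chains: Iterable[AlignedChain], end_fuzz: int = 100) -> list[IsoformRecord]:
    """Collapse accepted chains into unique isoforms with PB-style IDs.

    Deterministic and invariant to input order: loci are numbered by genomic
    position, isoforms within a locus by descending read support then
    coordinates.
    """
    by_strand: dict[tuple[str, str], list[AlignedChain]] = {}
    for c in chains:
        by_strand.setdefault((c.chrom, c.strand), []).append(c)

    # proto-isoforms: (chrom, strand, junctions, start, end, read_ids)
    protos: list[tuple[str, str, tuple, int, int, list[str]]] = []
    for (chrom, strand), group in by_strand.items():
        multi: dict[tuple, list[AlignedChain]] = {}
        mono: list[AlignedChain] = []
        for c in group:
            if c.junctions:
                multi.setdefault(c.junctions, []).append(c)
            else:
                mono.append(c)
        for juncs, members in multi.items():
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            protos.append((chrom, strand, juncs, start, end,
                           sorted(m.read_id for m in members)))
        for members in _merge_mono_exon(mono, end_fuzz):
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            protos.append((chrom, strand, (), start, end,
                           sorted(m.read_id for m in members)))

    # loci: connected components of span overlap per (chrom, strand)
    isoforms: list[IsoformRecord] = []
    locus_groups: list[tuple[str, int, list]] = []  # (chrom, locus_start, protos)
    for (chrom, strand) in sorted({(p[0], p[1]) for p in protos}):
        members = sorted((p for p in protos if p[0] == chrom and p[1] == strand),
                         key=lambda p: (p[3], p[4]))
        current: list = []
        cur_end = -1
        for p in members:
            if current and p[3] >= cur_end:
                locus_groups.append((chrom, current[0][3], current))
                current = []
            current.append(p)
            cur_end = max(cur_end, p[4])
        if current:
            locus_groups.append((chrom, current[0][3], current))

    locus_groups.sort(key=lambda g: (g[0], g[1]))
    for locus_no, (_chrom, _start, members) in enumerate(locus_groups, start=1):
        members.sort(key=lambda p: (-len(p[5]), p[3], p[4], p[2]))
        for idx, (chrom, strand, juncs, start, end, read_ids) in enumerate(members, start=1):
            isoforms.append(IsoformRecord(
                isoform_id=f"PB.{locus_no}.{idx}",
                chrom=chrom, strand=strand, junctions=juncs,
                start=start, end=end, read_ids=read_ids,
            ))
    return isoforms
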