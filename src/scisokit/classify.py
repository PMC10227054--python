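"""SQANTI-style structural classification and artifact filtering.

A discovered isoform is assigned to the same-strand gene with maximal exonic
overlap and given exactly one category:

* FSM  — junction chain equals a reference transcript's chain;
* ISM  — chain is a consecutive proper subchain of a reference chain;
* NIC  — novel chain using only annotated donors and acceptors of the gene;
* NNC  — chain using at least one unannotated splice site;
* antisense / fusion / genic / genic_intron / intergenic — no same-strand
  exonic overlap, resolved in that order.

Artifact filters follow the source protocol: novel junctions must carry a
canonical intron motif (GT-AG / GC-AG / AT-AC on the transcribed strand) and
must not show a direct-repeat RT-template-switching signature; ISM/NIC/NNC
isoforms are retained only when both transcript ends fall within ``window``
(default 50 nt) of a CAGE (5') or polyA (3') peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .annotation import (
    Annotation,
    GeneModel,
    Genome,
    Junction,
    exons_from_chain,
    junction_chain,
    revcomp,
)

CANONICAL_MOTIFS = frozenset({"GTAG", "GCAG", "ATAC"})
CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "antisense", "fusion", "genic",
              "genic_intron", "intergenic")
NOVEL_CATEGORIES = frozenset({"NIC", "NNC"})
DEFAULT_FILTERED = frozenset({"ISM", "NIC", "NNC"})


@dataclass
class CategoryCall:
    category: str
    gene_id: str | None = None
    ref_transcript_id: str | None = None  # FSM/ISM evidence
    novel_donors: tuple[int, ...] = ()
    novel_acceptors: tuple[int, ...] = ()


@dataclass
class FilterFlags:
    cage_supported: bool
    polya_supported: bool
    noncanonical_novel_junction: bool
    rt_switch: bool
    retained: bool


def _is_infix(sub: tuple, full: tuple) -> bool:
    """True when `sub` is a consecutive *proper* subsequence of `full`."""
    n, m = len(sub), len(full)
    if n == 0 or n >= m:
        return False
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def _exonic_overlap(query_exons, gene: GeneModel) -> int:
    total = 0
    for qe in query_exons:
        covered: list[tuple[int, int]] = []
        for t in gene.transcripts:
            for ge in t.exons:
                s, e = max(qe.start, ge.start), min(qe.end, ge.end)
                if s < e:
                    covered.append((s, e))
        # merge to avoid double counting overlapping reference exons
        covered.sort()
        last_end = -1
        for s, e in covered:
            if s > last_end:
                total += e - s
                last_end = e
            elif e > last_end:
                total += e - last_end
                last_end = e
    return total


def classify(
    chrom: str,
    strand: str,
    start: int,
    end: int,
    junctions: tuple[Junction, ...],
    annotation: Annotation,
    mono_end_fuzz: int = 100,
) -> CategoryCall:
    """Assign a gene and structural category to one discovered isoform."""
    if chrom not in annotation._by_chrom:
        logging.getLogger(__name__).warning(
            "query on unknown chromosome %s: intergenic", chrom)
        return CategoryCall("intergenic")
    query_exons = exons_from_chain(chrom, start, end, junctions, strand)
    same = annotation.overlapping_genes(chrom, start, end, strand)
    scored = [(g, _exonic_overlap(query_exons, g)) for g in same]
    scored = [(g, s) for g, s in scored if s > 0]
    if scored:
        scored.sort(key=lambda gs: (-gs[1], gs[0].gene_id))
        gene = scored[0][0]
        if junctions:
            return _classify_multi_exon(gene, strand, junctions, annotation)
        return _classify_mono_exon(gene, start, end, mono_end_fuzz)

    # no same-strand exonic overlap
    opposite = annotation.overlapping_genes(chrom, start, end,
                                            "-" if strand == "+" else "+")
    if any(_exonic_overlap(query_exons, g) > 0 for g in opposite):
        return CategoryCall("antisense")
    loci = annotation.overlapping_genes(chrom, start, end)
    if junctions and len(loci) >= 2 and _pairwise_disjoint(loci):
        return CategoryCall("fusion")
    for g in loci:
        for t in g.transcripts:
            for a, b in zip(t.exons, t.exons[1:]):
                if a.end <= start and end <= b.start:
                    return CategoryCall("genic_intron", gene_id=g.gene_id)
    if loci:
        return CategoryCall("genic", gene_id=loci[0].gene_id)
    return CategoryCall("intergenic")


def _pairwise_disjoint(genes) -> bool:
    spans = sorted((g.start, g.end) for g in genes)
    return all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))


def _classify_multi_exon(gene: GeneModel, strand: str,
                         junctions: tuple[Junction, ...],
                         annotation: Annotation) -> CategoryCall:
    ism_hit = None
    for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
        ref = junction_chain(t).junctions
        if junctions == ref:
            return CategoryCall("FSM", gene_id=gene.gene_id, ref_transcript_id=t.transcript_id)
        if ism_hit is None and _is_infix(junctions, ref):
            ism_hit = t.transcript_id
    if ism_hit is not None:
        return CategoryCall("ISM", gene_id=gene.gene_id, ref_transcript_id=ism_hit)
    sites = annotation.sites(gene.gene_id)
    novel_donors, novel_acceptors = [], []
    for left, right in junctions:
        donor, acceptor = (left, right) if strand == "+" else (right, left)
        if donor not in sites.donors:
            novel_donors.append(donor)
        if acceptor not in sites.acceptors:
            novel_acceptors.append(acceptor)
    if novel_donors or novel_acceptors:
        return CategoryCall("NNC", gene_id=gene.gene_id,
                            novel_donors=tuple(novel_donors),
                            novel_acceptors=tuple(novel_acceptors))
    return CategoryCall("NIC", gene_id=gene.gene_id)


def _classify_mono_exon(gene: GeneModel, start: int, end: int, fuzz: int) -> CategoryCall:
    for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
        if len(t.exons) == 1 and abs(t.start - start) <= fuzz and abs(t.end - end) <= fuzz:
            return CategoryCall("FSM", gene_id=gene.gene_id, ref_transcript_id=t.transcript_id)
    for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
        for e in t.exons:
            if e.start <= start and end <= e.end:
                return CategoryCall("ISM", gene_id=gene.gene_id, ref_transcript_id=t.transcript_id)
    return CategoryCall("genic", gene_id=gene.gene_id)


def junction_artifact_check(
    chrom: str,
    strand: str,
    junctions: tuple[Junction, ...],
    genome: Genome,
    annotated_junctions: frozenset[Junction] | None = None,
    repeat_k: int = 8,
    canonical: frozenset[str] = CANONICAL_MOTIFS,
) -> tuple[bool, bool]:
    """Flag novel junctions that are non-canonical or RT-template-switch-like.

    A junction absent from ``annotated_junctions`` (all junctions, when None)
    is read off the genome: its intron dinucleotides on the transcribed strand
    must be one of the canonical motifs, and an identical ``repeat_k``-mer
    ending at the donor (exonic side) and at the acceptor's intronic boundary
    marks a direct-repeat template-switching signature.
    """
    noncanonical = False
    rt_switch = False
    known = annotated_junctions or frozenset()
    contig_len = len(genome.sequences[chrom])
    for left, right in junctions:
        if (left, right) in known:
            continue
        if left - 2 < 0 or right + 2 > contig_len:
            raise ValueError(f"junction ({left},{right}) off the end of {chrom}")
        intron = genome.fetch(chrom, left, right)
        if strand == "-":
            intron = revcomp(intron)
        if intron[:2] + intron[-2:] not in canonical:
            noncanonical = True
        if strand == "+":
            if left - repeat_k >= 0 and genome.fetch(chrom, left - repeat_k, left) == \
                    genome.fetch(chrom, right - repeat_k, right):
                rt_switch = True
        else:
            if right + repeat_k <= contig_len and genome.fetch(chrom, right, right + repeat_k) == \
                    genome.fetch(chrom, left, left + repeat_k):
                rt_switch = True
    return noncanonical, rt_switch


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    strand: str


def _peak_distance(pos: int, peak: Peak) -> int:
    if peak.start <= pos < peak.end:
        return 0
    return peak.start - pos if pos < peak.start else pos - (peak.end - 1)


def _end_supported(chrom: str, strand: str, pos: int, peaks, window: int) -> bool:
    return any(
        p.chrom == chrom and p.strand == strand and _peak_distance(pos, p) <= window
        for p in peaks
    )


def end_support_filter(
    category: str,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    cage_peaks,
    polya_peaks,
    noncanonical_novel_junction: bool = False,
    rt_switch: bool = False,
    window: int = 50,
    categories_filtered: frozenset[str] = DEFAULT_FILTERED,
) -> FilterFlags:
    """Apply the end-support retention rule.

    The TSS must lie within ``window`` of a CAGE peak and the TES within
    ``window`` of a polyA peak (strand-aware; distance 0 inside a peak);
    categories outside ``categories_filtered`` (by default FSM) are exempt.
    """
    tss = start if strand == "+" else end - 1
    tes = end - 1 if strand == "+" else start
    cage_ok = _end_supported(chrom, strand, tss, cage_peaks, window)
    polya_ok = _end_supported(chrom, strand, tes, polya_peaks, window)
    retained = category not in categories_filtered or (
        cage_ok and polya_ok and not noncanonical_novel_junction and not rt_switch
    )
    return FilterFlags(cage_ok, polya_ok, noncanonical_novel_junction, rt_switch, retained)


def read_bed_peaks(path) -> list[Peak]:
    """Read a BED file of peaks (chrom, start, end, name, score, strand)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "+"
            peaks.append(Peak(f[0], int(f[1]), int(f[2]), strand))
    return peaks
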