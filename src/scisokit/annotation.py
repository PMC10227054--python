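"""Genomic interval and transcript data model, junction-chain algebra, GTF/FASTA I/O.

Internal coordinates are 0-based half-open throughout; GTF I/O converts to and
from the 1-based inclusive convention of the format. Exon lists are stored in
genomic order regardless of strand; biological (transcription) order is derived
on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pyfaidx

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-annotated half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


# A junction is (donor_pos, acceptor_pos) in genomic coordinates:
# donor_pos = end of the upstream (leftward) exon, acceptor_pos = start of the
# downstream exon. On the minus strand the *biological* donor is the right
# coordinate; helpers below relabel strand-aware.
Junction = tuple[int, int]


@dataclass(frozen=True)
class JunctionChain:
    """Ordered splice junctions of a (possibly mono-exonic) transcript."""

    chrom: str
    strand: str
    junctions: tuple[Junction, ...]

    def __post_init__(self) -> None:
        prev = -1
        for left, right in self.junctions:
            if not left < right:
                raise ValueError(f"junction ({left},{right}) not increasing")
            if left <= prev:
                raise ValueError("junctions not strictly increasing")
            prev = right

    def __len__(self) -> int:
        return len(self.junctions)

    @property
    def is_mono_exonic(self) -> bool:
        return not self.junctions


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    cds: tuple[int, int] | None = None  # transcript coordinates, half-open

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons span multiple chromosomes")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} / {b}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def biological_exons(self) -> list[GenomicInterval]:
        """Exons in transcription (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def sequence(self, genome: "Genome") -> str:
        """Spliced mature sequence, 5'->3' on the sense strand."""
        s = "".join(genome.fetch(e.chrom, e.start, e.end) for e in self.exons)
        return s if self.strand == "+" else revcomp(s)


def junction_chain(t: TranscriptModel) -> JunctionChain:
    """Splice-junction chain of a transcript; empty iff mono-exonic."""
    juncs = tuple(
        (a.end, b.start) for a, b in zip(t.exons, t.exons[1:])
    )
    return JunctionChain(t.chrom, t.strand, juncs)


def exons_from_chain(
    chrom: str, start: int, end: int, junctions: Sequence[Junction], strand: str = "+"
) -> list[GenomicInterval]:
    """Reconstruct the exon list from a transcript span plus its junctions.

    Inverse of :func:`junction_chain` given the span: n junctions -> n+1 exons.
    """
    bounds = [start]
    for left, right in junctions:
        bounds.extend((left, right))
    bounds.append(end)
    return [
        GenomicInterval(chrom, s, e, strand) for s, e in zip(bounds[::2], bounds[1::2])
    ]


@dataclass(frozen=True)
class SiteCatalog:
    """Strand-aware splice-site sets of a gene (donor = 5' site by strand)."""

    donors: frozenset[int]
    acceptors: frozenset[int]
    junctions: frozenset[Junction]


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


def site_catalog(gene: GeneModel) -> SiteCatalog:
    """Union of donor/acceptor/junction sets over a gene's transcripts.

    On the minus strand the biological donor of a junction (left, right) is the
    `right` genomic coordinate, so donor/acceptor labels swap relative to
    genomic left/right.
    """
    donors: set[int] = set()
    acceptors: set[int] = set()
    junctions: set[Junction] = set()
    for t in gene.transcripts:
        for left, right in junction_chain(t).junctions:
            junctions.add((left, right))
            if gene.strand == "+":
                donors.add(left)
                acceptors.add(right)
            else:
                donors.add(right)
                acceptors.add(left)
    return SiteCatalog(frozenset(donors), frozenset(acceptors), frozenset(junctions))


class Annotation:
    """A set of gene models with simple per-chromosome overlap queries."""

    def __init__(self, genes: Iterable[GeneModel], source: str = "reference") -> None:
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.source = source
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))
        self._sites: dict[str, SiteCatalog] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes.values():
            yield from g.transcripts

    def overlapping_genes(self, chrom: str, start: int, end: int,
                          strand: str | None = None) -> list[GeneModel]:
        out = []
        for g in self._by_chrom.get(chrom, []):
            if g.start < end and start < g.end and (strand is None or g.strand == strand):
                out.append(g)
        return out

    def sites(self, gene_id: str) -> SiteCatalog:
        if gene_id not in self._sites:
            self._sites[gene_id] = site_catalog(self.genes[gene_id])
        return self._sites[gene_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        if set(self.genes) != set(other.genes):
            return False
        for gid, g in self.genes.items():
            h = other.genes[gid]
            if g.strand != h.strand:
                return False
            ts1 = {t.transcript_id: t.exons for t in g.transcripts}
            ts2 = {t.transcript_id: t.exons for t in h.transcripts}
            if ts1 != ts2:
                return False
        return True


def _parse_gtf_attributes(blob: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in blob.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, val = parts
        attrs[key] = val.strip().strip('"')
    return attrs


def read_annotation(gtf_path, source: str = "reference") -> Annotation:
    """Read exon features from a GTF into an :class:`Annotation`.

    1-based inclusive GTF coordinates become 0-based half-open. Transcripts
    with overlapping exons are rejected and logged; structurally malformed
    lines raise :class:`GtfParseError` naming the line number.
    """
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, strand)
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_blob = fields
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_blob, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon feature missing transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon feature missing gene_id")
            tid = attrs["transcript_id"]
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            exons_by_tid.setdefault(tid, []).append(iv)
            meta[tid] = (attrs["gene_id"], strand)

    genes: dict[str, GeneModel] = {}
    for tid, exons in exons_by_tid.items():
        gene_id, strand = meta[tid]
        try:
            t = TranscriptModel(tid, gene_id, strand, exons)
        except ValueError as exc:
            logger.warning("rejecting transcript %s: %s", tid, exc)
            continue
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, strand)
        genes[gene_id].transcripts.append(t)
    for g in genes.values():
        g.transcripts.sort(key=lambda t: (t.start, t.end, t.transcript_id))
    return Annotation(genes.values(), source=source)


def write_annotation(annotation: Annotation, gtf_path, source_tag: str = "scisokit") -> None:
    """Write transcript+exon GTF lines with deterministic attribute order."""
    with open(gtf_path, "w") as fh:
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            for t in sorted(gene.transcripts, key=lambda t: (t.start, t.end, t.transcript_id)):
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\t{source_tag}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\t{source_tag}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )


class Genome:
    """In-memory genome with a FASTA reader/writer.

    Small synthetic genomes fit comfortably in memory; `from_fasta` uses
    pyfaidx so that arbitrary reference FASTAs load the same way.
    """

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self.sequences = dict(sequences)

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(f"interval {chrom}:{start}-{end} off contig end (len {len(seq)})")
        return seq[start:end]

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
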