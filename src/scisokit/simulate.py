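"""Synthetic single-cell long-read experiment with full ground truth.

Emulates a desk-scale ScISOr-Seq-style experiment: a small multi-gene genome
and annotation, novel isoforms generated by defined alternative-splicing
perturbations, cluster-structured expression over barcoded cells, full-length
reads carrying primers / polyA tails / UMIs / cell barcodes (with optional 5'
truncation and single-substitution barcode errors), companion spliced
alignments, short-read junction support counts, CAGE and polyA end-support
peaks, tryptic peptides with decoys — and a TruthManifest recording the
provenance of every isoform and read so each pipeline stage can be tested
without any external data.

Everything is deterministic under (config, seed): two runs with the same
configuration produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import (
    Annotation,
    GeneModel,
    Genome,
    GenomicInterval,
    TranscriptModel,
    junction_chain,
    revcomp,
    site_catalog,
    write_annotation,
)
from .demux import PRIMER_3P, PRIMER_5P
from .orf import predict_orf, tryptic_peptides

NT = np.array(list("ACGT"))
SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
EVENT_KINDS = ("ES", "A5", "A3", "AF", "AL", "RI", "MX", "novel_exon")
CLUSTER_NAMES = ("IHC", "OHC", "DC_PC", "TBC", "FC", "RMC", "CEC", "IPhC_IBC")


def _default_event_mix() -> dict[str, float]:
    return {"ES": 0.30, "A5": 0.10, "A3": 0.10, "AF": 0.07, "AL": 0.07,
            "RI": 0.16, "MX": 0.08, "novel_exon": 0.12}


@dataclass
class SimulationConfig:
    """Stated world of the toy experiment.

    Defaults describe a 20-gene, 4-cluster, 200-cell experiment with ~20k
    reads (about 100 reads per cell), 10x-V3-style 16-nt barcodes and 12-nt
    UMIs, and a >=20-nt polyA tail on every full-length read.
    """

    seed: int = 0
    n_genes: int = 20
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (100, 400)
    n_clusters: int = 4
    cells_per_cluster: int = 50
    novel_isoform_fraction: float = 0.5
    event_mix: dict[str, float] = field(default_factory=_default_event_mix)
    reads_per_cell_mean: float = 100.0
    truncation_prob: float = 0.05
    barcode_error_rate: float = 0.01
    pcr_duplicate_rate: float = 0.10
    polya_length: int = 30
    barcode_length: int = 16
    umi_length: int = 12
    utr5_length: int = 30
    utr3_length: int = 30
    cluster_exclusive_prob: float = 0.7
    short_read_depth: float = 3.0
    peptides_per_isoform: int = 3
    n_decoy_peptides: int = 30
    min_orf_codons: int = 100
    gene_gap: tuple[int, int] = (500, 1500)

    def __post_init__(self) -> None:
        for name in ("truncation_prob", "barcode_error_rate", "pcr_duplicate_rate",
                     "cluster_exclusive_prob", "novel_isoform_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_mix probabilities must sum to 1")
        if set(self.event_mix) - set(EVENT_KINDS):
            raise ValueError(f"unknown event kinds {set(self.event_mix) - set(EVENT_KINDS)}")
        for name in ("exon_length", "intron_length", "transcripts_per_gene",
                     "exons_per_transcript", "gene_gap"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name}=({lo},{hi}) must be positive and ordered")
        if self.exons_per_transcript[0] < 2:
            raise ValueError("transcripts need >=2 exons for splice perturbations")


class PatchConflict(Exception):
    pass


class MutableGenome:
    """Character-level mutable genome with conflict-guarded motif patches."""

    def __init__(self) -> None:
        self.seqs: dict[str, list[str]] = {}
        self._patches: dict[tuple[str, int], str] = {}

    def write(self, chrom: str, pos: int, s: str) -> None:
        buf = self.seqs[chrom]
        buf[pos : pos + len(s)] = list(s)

    def patch(self, chrom: str, pos: int, s: str) -> None:
        """Write a splice motif, refusing to overwrite a different prior patch."""
        for i, c in enumerate(s):
            key = (chrom, pos + i)
            if key in self._patches and self._patches[key] != c:
                raise PatchConflict(f"{chrom}:{pos + i} already patched")
        for i, c in enumerate(s):
            self._patches[(chrom, pos + i)] = c
        self.write(chrom, pos, s)

    def freeze(self) -> Genome:
        return Genome({c: "".join(b) for c, b in self.seqs.items()})


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, n)])


def _design_spliced_sequence(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> str:
    """Sense-strand mature sequence with a planted long ORF when room allows."""
    coding_space = length - cfg.utr5_length - cfg.utr3_length
    n_aa = (coding_space - 3) // 3 if coding_space > 6 else 0
    if n_aa < 2:
        return _random_seq(rng, length)
    codon_idx = rng.integers(0, len(SENSE_CODONS), n_aa - 1)
    body = "ATG" + "".join(SENSE_CODONS[i] for i in codon_idx) + "TAA"
    tail = length - cfg.utr5_length - len(body)
    return _random_seq(rng, cfg.utr5_length) + body + _random_seq(rng, max(0, tail))


def _layout_gene(rng, cfg, chrom, cursor, gene_id):
    """Place one gene's exon/intron skeleton; returns (gene, next_cursor)."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
    exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_ex)
    intron_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, max(0, n_ex - 1))
    exons = []
    pos = cursor
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
        pos += int(el)
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    t1 = TranscriptModel(f"{gene_id}.T1", gene_id, strand, exons)
    gene = GeneModel(gene_id, strand, [t1])

    n_t = int(rng.integers(cfg.transcripts_per_gene[0], cfg.transcripts_per_gene[1] + 1))
    chains = {junction_chain(t1).junctions}
    k = 2
    for _ in range(n_t - 1):
        if n_ex < 3:
            break
        for _attempt in range(10):
            skip = int(rng.integers(1, n_ex - 1))
            variant = [e for i, e in enumerate(exons) if i != skip]
            key = junction_chain(TranscriptModel("x", gene_id, strand, list(variant))).junctions
            if key not in chains:
                chains.add(key)
                gene.transcripts.append(
                    TranscriptModel(f"{gene_id}.T{k}", gene_id, strand, list(variant)))
                k += 1
                break
    return gene, pos


def simulate_reference(cfg: SimulationConfig, rng: np.random.Generator | None = None
                       ) -> tuple[MutableGenome, Annotation]:
    """Build the toy genome and reference annotation.

    Genes are non-overlapping on a single contig; every annotated intron
    carries the canonical GT-AG dinucleotides on the transcribed strand.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    chrom = "chr1"
    genome = MutableGenome()
    genes: list[GeneModel] = []
    cursor = int(rng.integers(*cfg.gene_gap))
    for g in range(cfg.n_genes):
        gene, end = _layout_gene(rng, cfg, chrom, cursor, f"G{g + 1:03d}")
        genes.append(gene)
        cursor = end + int(rng.integers(*cfg.gene_gap))
    total_len = cursor + 200
    genome.seqs[chrom] = list(_random_seq(rng, total_len))

    for gene in genes:
        t1 = gene.transcripts[0]
        spliced = _design_spliced_sequence(rng, t1.spliced_length(), cfg)
        chunks = []
        off = 0
        for e in t1.biological_exons():
            chunks.append((e, spliced[off : off + len(e)]))
            off += len(e)
        for e, chunk in chunks:
            genome.write(e.chrom, e.start, chunk if gene.strand == "+" else revcomp(chunk))
        for a, b in zip(t1.exons, t1.exons[1:]):
            if gene.strand == "+":
                genome.patch(chrom, a.end, "GT")
                genome.patch(chrom, b.start - 2, "AG")
            else:
                genome.patch(chrom, a.end, "CT")
                genome.patch(chrom, b.start - 2, "AC")
    return genome, Annotation(genes, source="reference")


@dataclass
class NovelTruth:
    origin: str  # perturbation kind
    intended_category: str  # NIC | NNC


def _intended_category(chain, strand: str, gene_sites) -> str:
    for left, right in chain:
        donor, acceptor = (left, right) if strand == "+" else (right, left)
        if donor not in gene_sites.donors or acceptor not in gene_sites.acceptors:
            return "NNC"
    return "NIC"


def _perturb(rng, cfg, genome, host: TranscriptModel, kind: str,
             strand: str) -> list[GenomicInterval] | None:
    """One perturbed exon list, patching novel splice motifs; None if infeasible."""
    exons = list(host.exons)
    n = len(exons)
    chrom = host.chrom
    new_len = 60

    if kind == "ES":
        if n < 3:
            return None
        i = int(rng.integers(1, n - 1))
        return [e for j, e in enumerate(exons) if j != i]

    if kind == "RI":
        if n < 4:  # interior junction needed, else chain degenerates to an infix
            return None
        k = int(rng.integers(1, n - 2))
        merged = GenomicInterval(chrom, exons[k].start, exons[k + 1].end, strand)
        return exons[:k] + [merged] + exons[k + 2 :]

    if kind in ("A5", "A3"):
        k = int(rng.integers(0, n - 1))
        left, right = exons[k].end, exons[k + 1].start
        if right - left < 60:
            return None
        delta = int(rng.integers(6, 21))
        shift_left = (kind == "A5") == (strand == "+")  # move the genomic-left boundary
        if shift_left:
            pos = left + delta
            genome.patch(chrom, pos, "GT" if strand == "+" else "CT")
            exons[k] = GenomicInterval(chrom, exons[k].start, pos, strand)
        else:
            pos = right - delta
            genome.patch(chrom, pos - 2, "AG" if strand == "+" else "AC")
            exons[k + 1] = GenomicInterval(chrom, pos, exons[k + 1].end, strand)
        return exons

    if kind in ("AF", "AL"):
        # replace the biological first (AF) or last (AL) exon with a new exon
        # placed inside the adjacent intron
        at_genomic_left = (kind == "AF") == (strand == "+")
        if at_genomic_left:
            left, right = exons[0].end, exons[1].start
            if right - left < new_len + 30:
                return None
            ns = left + int(rng.integers(8, right - left - new_len - 16))
            ne = ns + new_len
            genome.patch(chrom, ne, "GT" if strand == "+" else "CT")
            return [GenomicInterval(chrom, ns, ne, strand)] + exons[1:]
        left, right = exons[-2].end, exons[-1].start
        if right - left < new_len + 30:
            return None
        ns = left + int(rng.integers(8, right - left - new_len - 16))
        ne = ns + new_len
        genome.patch(chrom, ns - 2, "AG" if strand == "+" else "AC")
        return exons[:-1] + [GenomicInterval(chrom, ns, ne, strand)]

    if kind in ("MX", "novel_exon"):
        if kind == "MX" and n < 3:
            return None
        if kind == "MX":
            i = int(rng.integers(1, n - 1))  # internal exon to swap out
            left, right = exons[i].end, exons[i + 1].start if i + 1 < n else None
            if right is None or right - left < new_len + 30:
                return None
        else:
            i = int(rng.integers(0, n - 1))  # intron to insert into
            left, right = exons[i].end, exons[i + 1].start
            if right - left < new_len + 30:
                return None
        ns = left + int(rng.integers(8, right - left - new_len - 16))
        ne = ns + new_len
        genome.patch(chrom, ns - 2, "AG" if strand == "+" else "AC")
        genome.patch(chrom, ne, "GT" if strand == "+" else "CT")
        new_exon = GenomicInterval(chrom, ns, ne, strand)
        if kind == "MX":
            return [e for j, e in enumerate(exons) if j != i][:i] + [new_exon] + exons[i + 1 :]
        return exons[: i + 1] + [new_exon] + exons[i + 1 :]

    raise ValueError(f"unknown perturbation kind {kind!r}")


def _is_infix(sub, full) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n >= m:
        return False
    return any(tuple(full[i : i + n]) == tuple(sub) for i in range(m - n + 1))


def simulate_novel_isoforms(
    genome: MutableGenome,
    annotation: Annotation,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    max_retries: int = 60,
) -> tuple[list[TranscriptModel], dict[str, NovelTruth]]:
    """Generate novel isoforms as defined perturbations of reference transcripts.

    The intended structural category is recorded per isoform from the splice
    sites it uses: NIC when every donor/acceptor is annotated for the host
    gene, NNC otherwise. No novel isoform duplicates (or is a consecutive
    subchain of) any reference chain.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    kinds = sorted(cfg.event_mix)
    probs = np.array([cfg.event_mix[k] for k in kinds])
    f = cfg.novel_isoform_fraction
    novels: list[TranscriptModel] = []
    truth: dict[str, NovelTruth] = {}
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        sites = site_catalog(gene)
        ref_chains = [junction_chain(t).junctions for t in gene.transcripts]
        existing = set(ref_chains)
        n_ref = len(gene.transcripts)
        n_novel = int(round(f / (1.0 - f) * n_ref)) if f < 1.0 else n_ref
        made = 0
        for k in range(n_novel):
            for _attempt in range(max_retries):
                kind = kinds[int(rng.choice(len(kinds), p=probs))]
                host = gene.transcripts[int(rng.integers(0, n_ref))]
                try:
                    exons = _perturb(rng, cfg, genome, host, kind, gene.strand)
                except PatchConflict:
                    continue
                if exons is None:
                    continue
                try:
                    t = TranscriptModel(f"{gid}.N{made + 1}", gid, gene.strand, exons)
                except ValueError:
                    continue
                chain = junction_chain(t).junctions
                if not chain or chain in existing:
                    continue
                if any(_is_infix(chain, rc) for rc in ref_chains):
                    continue
                existing.add(chain)
                novels.append(t)
                truth[t.transcript_id] = NovelTruth(
                    kind, _intended_category(chain, gene.strand, sites))
                made += 1
                break
    return novels, truth


@dataclass
class TruthManifest:
    """Ground truth of one simulated experiment (JSON-serializable)."""

    isoforms: dict[str, dict]
    reads: dict[str, dict]
    junctions: list[dict]
    decoy_peptides: list[str]
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def expressed_chain_set(self) -> set[tuple]:
        return {
            (info["chrom"], info["strand"], tuple(map(tuple, info["chain"])))
            for info in self.isoforms.values()
            if info["n_molecules"] > 0 and info["chain"]
        }


@dataclass
class SimulatedExperiment:
    outdir: Path
    genome_fasta: Path
    annotation_gtf: Path
    reads_fastq: Path
    alignments_sam: Path
    whitelist_tsv: Path
    clusters_tsv: Path
    junction_counts_tsv: Path
    cage_bed: Path
    polya_bed: Path
    peptides_txt: Path
    truth_json: Path
    manifest: TruthManifest


def _make_whitelist(rng, n_cells: int, bc_len: int) -> list[str]:
    """Barcodes at pairwise Hamming distance >=3 (single errors uniquely correctable)."""
    out: list[str] = []
    while len(out) < n_cells:
        cand = _random_seq(rng, bc_len)
        if all(sum(a != b for a, b in zip(cand, w)) >= 3 for w in out):
            out.append(cand)
    return out


def _truncate(rng, t: TranscriptModel) -> tuple[list[GenomicInterval], bool]:
    """Drop a 5' portion, cutting inside an internal exon (chain becomes a suffix)."""
    bio = t.biological_exons()
    if len(bio) < 2:
        return list(t.exons), False
    j = int(rng.integers(1, len(bio)))
    exon = bio[j]
    if len(exon) < 12:
        return list(t.exons), False
    cut = int(rng.integers(5, len(exon) - 5))
    if t.strand == "+":
        remaining = [GenomicInterval(exon.chrom, exon.start + cut, exon.end, t.strand)] \
            + [e for e in t.exons if e.start > exon.start]
    else:
        remaining = [e for e in t.exons if e.end < exon.end] \
            + [GenomicInterval(exon.chrom, exon.start, exon.end - cut, t.strand)]
    return remaining, True


def _cigar(exons: list[GenomicInterval]) -> str:
    parts = []
    for i, e in enumerate(exons):
        if i:
            parts.append(f"{e.start - exons[i - 1].end}N")
        parts.append(f"{len(e)}M")
    return "".join(parts)


def simulate_experiment(
    genome: MutableGenome,
    annotation: Annotation,
    novels: list[TranscriptModel],
    novel_truth: dict[str, NovelTruth],
    cfg: SimulationConfig,
    outdir,
    rng: np.random.Generator | None = None,
) -> SimulatedExperiment:
    """Emit the nine experiment files plus the truth manifest."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frozen = genome.freeze()

    isoforms: list[TranscriptModel] = sorted(
        list(annotation.transcripts()) + list(novels), key=lambda t: t.transcript_id
    )
    iso_by_id = {t.transcript_id: t for t in isoforms}
    weights = {t.transcript_id: float(rng.lognormal(0.0, 0.5)) for t in isoforms}

    clusters = [CLUSTER_NAMES[i] if i < len(CLUSTER_NAMES) else f"C{i + 1}"
                for i in range(cfg.n_clusters)]
    intended: dict[str, list[str]] = {}
    for t in isoforms:
        if t.transcript_id in novel_truth:
            if rng.random() < cfg.cluster_exclusive_prob:
                chosen = [clusters[int(rng.integers(0, cfg.n_clusters))]]
            else:
                chosen = sorted(
                    clusters[int(i)] for i in rng.choice(cfg.n_clusters, 2, replace=False))
            intended[t.transcript_id] = [str(c) for c in chosen]
        else:
            intended[t.transcript_id] = list(clusters)

    n_cells = cfg.n_clusters * cfg.cells_per_cluster
    whitelist = _make_whitelist(rng, n_cells, cfg.barcode_length)
    cell_cluster = {bc: clusters[i // cfg.cells_per_cluster]
                    for i, bc in enumerate(whitelist)}

    pool_by_cluster = {
        cl: sorted(t.transcript_id for t in isoforms if cl in intended[t.transcript_id])
        for cl in clusters
    }

    # molecules then reads (PCR duplicates re-emit a molecule under a new read id)
    molecules: list[tuple[str, str, str]] = []  # (isoform, barcode, umi)
    for bc in whitelist:
        cl = cell_cluster[bc]
        pool = pool_by_cluster[cl]
        w = np.array([weights[t] for t in pool])
        w = w / w.sum()
        n_mol = int(rng.poisson(cfg.reads_per_cell_mean))
        for idx in rng.choice(len(pool), n_mol, p=w):
            molecules.append((pool[int(idx)], bc, _random_seq(rng, cfg.umi_length)))

    read_rows: list[dict] = []  # per sequenced read
    for mol_i, (iso_id, bc, umi) in enumerate(molecules):
        n_copies = 1 + (1 if rng.random() < cfg.pcr_duplicate_rate else 0)
        for copy in range(n_copies):
            read_rows.append({
                "molecule": mol_i, "isoform": iso_id, "barcode": bc, "umi": umi,
                "duplicate": copy > 0,
            })

    n_span: dict[tuple[str, int, int, str], int] = {}
    mol_count: dict[str, int] = {t.transcript_id: 0 for t in isoforms}
    realized: dict[str, set[str]] = {t.transcript_id: set() for t in isoforms}
    for iso_id, bc, umi in molecules:
        t = iso_by_id[iso_id]
        mol_count[iso_id] += 1
        realized[iso_id].add(cell_cluster[bc])
        for left, right in junction_chain(t).junctions:
            d, a = (left, right) if t.strand == "+" else (right, left)
            key = (t.chrom, d, a, t.strand)
            n_span[key] = n_span.get(key, 0) + 1

    # sequenced reads: FASTQ + true spliced alignments (SAM)
    fastq_records = []
    sam_rows = []
    reads_truth: dict[str, dict] = {}
    for i, row in enumerate(read_rows):
        t = iso_by_id[row["isoform"]]
        exons, truncated = (list(t.exons), False)
        if cfg.truncation_prob > 0 and rng.random() < cfg.truncation_prob:
            exons, truncated = _truncate(rng, t)
        part = TranscriptModel("x", t.gene_id, t.strand, exons)
        insert = part.sequence(frozen)

        bc_obs = row["barcode"]
        bc_error = False
        if cfg.barcode_error_rate > 0 and rng.random() < cfg.barcode_error_rate:
            pos = int(rng.integers(0, cfg.barcode_length))
            alt = NT[rng.integers(0, 4)]
            while alt == bc_obs[pos]:
                alt = NT[rng.integers(0, 4)]
            bc_obs = bc_obs[:pos] + alt + bc_obs[pos + 1 :]
            bc_error = True

        read_id = f"read{i:07d}"
        seq = (PRIMER_5P + insert + "A" * cfg.polya_length + row["umi"]
               + bc_obs + PRIMER_3P)
        flipped = bool(rng.random() < 0.5)
        if flipped:
            seq = revcomp(seq)
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        fastq_records.append(rec)
        sam_rows.append((read_id, part, insert))
        reads_truth[read_id] = {
            "isoform": row["isoform"], "barcode": row["barcode"], "umi": row["umi"],
            "truncated": truncated, "barcode_error": bc_error,
            "duplicate": row["duplicate"],
        }

    reads_fastq = outdir / "reads.fastq"
    with open(reads_fastq, "w") as fh:
        SeqIO.write(fastq_records, fh, "fastq")

    alignments_sam = outdir / "alignments.sam"
    chroms = sorted(frozen.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(frozen.sequences[c])} for c in chroms],
    }
    chrom_idx = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(alignments_sam), "wh", header=header) as sam:
        for read_id, part, insert in sam_rows:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = read_id
            a.flag = 16 if part.strand == "-" else 0
            a.reference_id = chrom_idx[part.chrom]
            a.reference_start = part.start
            a.mapping_quality = 60
            a.cigarstring = _cigar(part.exons)
            a.query_sequence = insert if part.strand == "+" else revcomp(insert)
            sam.write(a)

    genome_fasta = outdir / "genome.fa"
    frozen.to_fasta(genome_fasta)
    annotation_gtf = outdir / "annotation.gtf"
    write_annotation(annotation, annotation_gtf)

    whitelist_tsv = outdir / "whitelist.tsv"
    whitelist_tsv.write_text("".join(bc + "\n" for bc in whitelist))
    clusters_tsv = outdir / "clusters.tsv"
    clusters_tsv.write_text("barcode\tcluster\n" + "".join(
        f"{bc}\t{cell_cluster[bc]}\n" for bc in whitelist))

    junction_rows = []
    for (chrom, d, a, strand) in sorted(n_span):
        support = int(rng.poisson(cfg.short_read_depth * n_span[(chrom, d, a, strand)]))
        junction_rows.append({"chrom": chrom, "donor": d, "acceptor": a,
                              "strand": strand, "n_span": n_span[(chrom, d, a, strand)],
                              "support": support})
    junction_counts_tsv = outdir / "junction_counts.tsv"
    with open(junction_counts_tsv, "w") as fh:
        fh.write("chrom\tdonor\tacceptor\tstrand\tunique_count\n")
        for r in junction_rows:
            fh.write(f"{r['chrom']}\t{r['donor']}\t{r['acceptor']}\t{r['strand']}\t{r['support']}\n")

    cage, polya = set(), set()
    for t in isoforms:
        if mol_count[t.transcript_id] == 0:
            continue
        tss = t.start if t.strand == "+" else t.end - 1
        tes = t.end - 1 if t.strand == "+" else t.start
        cage.add((t.chrom, max(0, tss - 5), tss + 6, t.strand))
        polya.add((t.chrom, max(0, tes - 5), tes + 6, t.strand))
    cage_bed = outdir / "cage_peaks.bed"
    polya_bed = outdir / "polya_peaks.bed"
    for path, peaks, tag in ((cage_bed, cage, "cage"), (polya_bed, polya, "polya")):
        with open(path, "w") as fh:
            for n, (chrom, s, e, strand) in enumerate(sorted(peaks), 1):
                fh.write(f"{chrom}\t{s}\t{e}\t{tag}_{n}\t0\t{strand}\n")

    # peptides: tryptic samples from true ORFs of expressed isoforms, plus decoys
    proteins: dict[str, str] = {}
    for t in isoforms:
        orf = predict_orf(t.sequence(frozen), cfg.min_orf_codons, t.transcript_id)
        if orf is not None:
            proteins[t.transcript_id] = orf.protein
    sampled: set[str] = set()
    for t in isoforms:
        if mol_count[t.transcript_id] == 0 or t.transcript_id not in proteins:
            continue
        cands = sorted(set(tryptic_peptides(proteins[t.transcript_id])))
        if not cands:
            continue
        take = min(cfg.peptides_per_isoform, len(cands))
        for idx in rng.choice(len(cands), take, replace=False):
            sampled.add(cands[int(idx)])
    all_prot = list(proteins.values())
    decoys: list[str] = []
    pool = sorted(sampled) or ["MVLSPADKTNVK"]
    attempts = 0
    while len(decoys) < cfg.n_decoy_peptides and attempts < 10000:
        attempts += 1
        base = pool[int(rng.integers(0, len(pool)))]
        letters = list(base)
        rng.shuffle(letters)
        cand = "".join(letters)
        if cand in sampled or cand in decoys:
            continue
        if any(cand in p for p in all_prot):
            continue
        decoys.append(cand)
    peptides_txt = outdir / "peptides.txt"
    peptides_txt.write_text("".join(p + "\n" for p in sorted(sampled) + sorted(decoys)))

    iso_truth: dict[str, dict] = {}
    for t in isoforms:
        nt = novel_truth.get(t.transcript_id)
        iso_truth[t.transcript_id] = {
            "chrom": t.chrom, "strand": t.strand, "start": t.start, "end": t.end,
            "chain": [list(j) for j in junction_chain(t).junctions],
            "origin": nt.origin if nt else "reference",
            "category": nt.intended_category if nt else "FSM",
            "intended_clusters": intended[t.transcript_id],
            "realized_clusters": sorted(realized[t.transcript_id]),
            "n_molecules": mol_count[t.transcript_id],
        }
    manifest = TruthManifest(
        isoforms=iso_truth,
        reads=reads_truth,
        junctions=junction_rows,
        decoy_peptides=sorted(decoys),
        config=dataclasses.asdict(cfg),
    )
    truth_json = outdir / "truth.json"
    manifest.to_json(truth_json)

    return SimulatedExperiment(
        outdir=outdir, genome_fasta=genome_fasta, annotation_gtf=annotation_gtf,
        reads_fastq=reads_fastq, alignments_sam=alignments_sam,
        whitelist_tsv=whitelist_tsv, clusters_tsv=clusters_tsv,
        junction_counts_tsv=junction_counts_tsv, cage_bed=cage_bed,
        polya_bed=polya_bed, peptides_txt=peptides_txt, truth_json=truth_json,
        manifest=manifest,
    )


def simulate(cfg: SimulationConfig, outdir) -> SimulatedExperiment:
    """Run the three simulation stages under a single seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    genome, annotation = simulate_reference(cfg, rng)
    novels, truth = simulate_novel_isoforms(genome, annotation, cfg, rng)
    return simulate_experiment(genome, annotation, novels, truth, cfg, outdir, rng)
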