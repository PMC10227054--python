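"""End-to-end pipeline: demux -> collapse -> classify -> events -> ORFs ->
validation -> cell matrix -> report.

``run_all`` consumes the file set a real experiment (or the bundled
generator) provides and writes every stage table plus a machine-readable
report into one output directory. All orderings are deterministic: the same
inputs, parameters and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import events as evt
from . import matrix as mtx
from . import orf as orfmod
from .classify import (
    classify as classify_isoform,
    end_support_filter,
    junction_artifact_check,
    read_bed_peaks,
)
from .collapse import collapse_chains, read_sam
from .demux import dedup_umis, demux_reads
from .annotation import (
    Annotation,
    GeneModel,
    Genome,
    TranscriptModel,
    read_annotation,
    write_annotation,
)


@dataclass
class PipelineParams:
    min_polya: int = 20
    min_mapq: int = 20
    end_fuzz: int = 100
    end_support_window: int = 50
    repeat_k: int = 8
    min_unique_junction_reads: int = 5  # strict: validated iff count > this
    detect_min: int = 1
    min_orf_codons: int = 100
    categories_filtered: tuple[str, ...] = ("ISM", "NIC", "NNC")
    seed: int = 0


@dataclass
class PipelineResult:
    outdir: Path
    isoforms: list  # retained IsoformRecord objects, classification attached
    all_isoforms: list
    report: dict
    cell_matrix: mtx.CellMatrix | None
    tables: dict[str, Path] = field(default_factory=dict)


def _load_reads(fastq_path):
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        yield rec.id, str(rec.seq)


def run_all(
    annotation_gtf,
    genome_fasta,
    reads_fastq,
    alignments_sam,
    whitelist_tsv,
    clusters_tsv,
    junction_counts_tsv,
    cage_bed,
    polya_bed,
    peptides_txt,
    outdir,
    params: PipelineParams | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = read_annotation(annotation_gtf)
    genome = Genome.from_fasta(genome_fasta)
    whitelist = [l.strip() for l in open(whitelist_tsv) if l.strip()]
    cluster_df = pd.read_csv(clusters_tsv, sep="\t")
    barcode_clusters = dict(zip(cluster_df["barcode"], cluster_df["cluster"]))

    # 1. demultiplex raw reads into FLNC records
    flnc, rejected, reject_counts = demux_reads(
        _load_reads(reads_fastq), whitelist, min_polya=params.min_polya)
    flnc_by_id = {r.read_id: r for r in flnc}
    pd.DataFrame(
        [{"read_id": r.read_id, "barcode": r.barcode, "umi": r.umi,
          "orientation": r.orientation, "polya_len": r.polya_len} for r in flnc]
    ).to_csv(outdir / "flnc.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"read_id": r.read_id, "reason": r.reason} for r in rejected]
    ).to_csv(outdir / "rejected_reads.tsv", sep="\t", index=False)

    # 2. aligned chains, restricted to demultiplexed reads
    chains, align_rejects = read_sam(alignments_sam, min_mapq=params.min_mapq)
    chains = [c for c in chains if c.read_id in flnc_by_id]
    chain_key = {c.read_id: c.chain_key() for c in chains}

    # 3. UMI deduplication on (barcode, UMI, junction chain)
    molecules = dedup_umis(flnc, chain_key)
    mol_ids = {m.read_id for m in molecules}
    dedup_chains = [c for c in chains if c.read_id in mol_ids]

    # 4. collapse into unique isoforms
    all_isoforms = collapse_chains(dedup_chains, end_fuzz=params.end_fuzz)
    for iso in all_isoforms:
        counts: dict[str, int] = {}
        for rid in iso.read_ids:
            counts[flnc_by_id[rid].barcode] = counts.get(flnc_by_id[rid].barcode, 0) + 1
        iso.cell_counts = counts
    pd.DataFrame(
        [{"read_id": rid, "isoform_id": iso.isoform_id}
         for iso in all_isoforms for rid in iso.read_ids]
    ).to_csv(outdir / "read_isoform.tsv", sep="\t", index=False)

    # 5. classification + artifact/end-support filtering
    cage = read_bed_peaks(cage_bed)
    polya = read_bed_peaks(polya_bed)
    filtered_set = frozenset(params.categories_filtered)
    cls_rows = []
    for iso in all_isoforms:
        call = classify_isoform(iso.chrom, iso.strand, iso.start, iso.end,
                            iso.junctions, annotation, mono_end_fuzz=params.end_fuzz)
        iso.category = call.category
        iso.gene_id = call.gene_id
        known = annotation.sites(call.gene_id).junctions if call.gene_id else None
        noncanon, rt = junction_artifact_check(
            iso.chrom, iso.strand, iso.junctions, genome,
            annotated_junctions=known, repeat_k=params.repeat_k)
        flags = end_support_filter(
            call.category, iso.chrom, iso.strand, iso.start, iso.end, cage, polya,
            noncanonical_novel_junction=noncanon, rt_switch=rt,
            window=params.end_support_window, categories_filtered=filtered_set)
        excluded = call.category in ("antisense", "fusion", "genic",
                                     "genic_intron", "intergenic")
        iso.retained = flags.retained and not excluded
        cls_rows.append({
            "isoform_id": iso.isoform_id, "category": call.category,
            "gene_id": call.gene_id or "", "ref_transcript_id": call.ref_transcript_id or "",
            "cage_supported": flags.cage_supported, "polya_supported": flags.polya_supported,
            "noncanonical_novel_junction": flags.noncanonical_novel_junction,
            "rt_switch": flags.rt_switch, "excluded_category": excluded,
            "retained": iso.retained, "n_reads": iso.n_reads,
        })
    classification = pd.DataFrame(cls_rows).set_index("isoform_id")
    classification.to_csv(outdir / "classification.tsv", sep="\t")
    retained = [iso for iso in all_isoforms if iso.retained]
    write_annotation(_as_annotation(retained), outdir / "isoforms.gtf",
                     source_tag="scisokit")

    # 6. AS events over reference + retained discovered transcripts, per gene
    combined: dict[str, list[TranscriptModel]] = {
        gid: list(g.transcripts) for gid, g in annotation.genes.items()
    }
    novelty = {t.transcript_id: "known" for t in annotation.transcripts()}
    for iso in retained:
        if iso.gene_id is None:
            continue
        t = TranscriptModel(iso.isoform_id, iso.gene_id, iso.strand, iso.exons())
        combined.setdefault(iso.gene_id, []).append(t)
        novelty[iso.isoform_id] = "novel" if iso.category in ("NIC", "NNC") else "known"
    all_events = []
    for gid in sorted(combined):
        all_events.extend(evt.detect_events(combined[gid]))
    event_summary = evt.summarize_events(all_events, novelty)
    event_summary.to_csv(outdir / "event_summary.tsv", sep="\t")
    pd.DataFrame(
        [{"event_type": e.event_type, "gene_id": e.gene_id, "chrom": e.chrom,
          "strand": e.strand, "coords": ",".join(map(str, e.coords)),
          "inclusion": ";".join(sorted(e.inclusion)),
          "exclusion": ";".join(sorted(e.exclusion))} for e in all_events]
    ).to_csv(outdir / "events.tsv", sep="\t", index=False)

    # 7. ORFs, unique CDSs, peptide support
    ref_proteome: dict[str, str] = {}
    for t in annotation.transcripts():
        orf = orfmod.predict_orf(t.sequence(genome), params.min_orf_codons,
                                 t.transcript_id)
        if orf is not None:
            ref_proteome[t.transcript_id] = orf.protein
    orfs = []
    for iso in retained:
        t = TranscriptModel(iso.isoform_id, iso.gene_id or iso.isoform_id,
                            iso.strand, iso.exons())
        orf = orfmod.predict_orf(t.sequence(genome), params.min_orf_codons,
                                 iso.isoform_id)
        if orf is not None:
            orf.orf_type = orfmod.classify_orf(orf, iso.gene_id, ref_proteome)
            orfs.append(orf)
    iso_to_cds, cds_groups = orfmod.unique_cds(orfs)
    peptides = [l.strip() for l in open(peptides_txt) if l.strip()]
    matches, supported = orfmod.map_peptides(peptides, orfs, ref_proteome)
    with open(outdir / "orfs.fasta", "w") as fh:
        for orf in sorted(orfs, key=lambda o: o.isoform_id):
            fh.write(f">{orf.isoform_id} start={orf.orf_start} type={orf.orf_type}\n")
            fh.write(orf.protein + "\n")
    pd.DataFrame(
        [{"isoform_id": o.isoform_id, "cds_group": iso_to_cds[o.isoform_id],
          "orf_type": o.orf_type, "protein_length": len(o.protein),
          "peptide_supported": supported[o.isoform_id]} for o in orfs]
    ).to_csv(outdir / "cds_groups.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"peptide": m.peptide, "n_isoforms": len(m.matched_isoform_ids),
          "isoforms": ";".join(m.matched_isoform_ids),
          "in_reference_proteome": m.in_reference_proteome,
          "isoform_specific": m.isoform_specific} for m in matches]
    ).to_csv(outdir / "peptide_matches.tsv", sep="\t", index=False)

    # 8. junction validation, cell matrix, specificity
    support = mtx.JunctionSupport.from_tsv(junction_counts_tsv)
    validation = mtx.validate_junctions(retained, support,
                                        min_unique=params.min_unique_junction_reads)
    validation.to_csv(outdir / "junction_validation.tsv", sep="\t")
    assignments = []
    for iso in retained:
        for rid in iso.read_ids:
            rec = flnc_by_id[rid]
            assignments.append((iso.isoform_id, rec.barcode, rec.umi))
    cell_matrix = mtx.build_matrix(sorted(assignments), barcode_clusters)
    cell_matrix.to_mtx(str(outdir / "isoform_cell"))
    spec = mtx.specificity_sets(cell_matrix, detect_min=params.detect_min)
    categories = {iso.isoform_id: iso.category for iso in retained}
    gene_ids = {iso.isoform_id: iso.gene_id for iso in retained}
    report = pipeline_report(
        n_input_reads=len(flnc) + len(rejected),
        reject_counts=dict(reject_counts),
        align_rejects=align_rejects,
        n_flnc=len(flnc),
        n_molecules=len(molecules),
        classification=classification,
        event_summary=event_summary,
        validation=validation,
        categories=categories,
        gene_ids=gene_ids,
        spec=spec,
        cell_matrix=cell_matrix,
        orfs=orfs,
        supported=supported,
        matches=matches,
        params=params,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    tables = {p.stem: p for p in sorted(outdir.glob("*.tsv"))}
    return PipelineResult(outdir, retained, all_isoforms, report, cell_matrix, tables)


def _as_annotation(isoforms) -> Annotation:
    genes: dict[str, GeneModel] = {}
    for iso in isoforms:
        gid = iso.gene_id or f"novelGene_{iso.isoform_id.split('.')[1]}"
        t = TranscriptModel(iso.isoform_id, gid, iso.strand, iso.exons())
        genes.setdefault(gid, GeneModel(gid, iso.strand)).transcripts.append(t)
    return Annotation(genes.values(), source="discovered")


def pipeline_report(
    *,
    n_input_reads: int,
    reject_counts: dict,
    align_rejects: dict,
    n_flnc: int,
    n_molecules: int,
    classification: pd.DataFrame,
    event_summary: pd.DataFrame,
    validation: pd.DataFrame,
    categories: dict,
    gene_ids: dict,
    spec: mtx.SpecificityResult,
    cell_matrix: mtx.CellMatrix,
    orfs,
    supported: dict,
    matches,
    params: PipelineParams,
) -> dict:
    """Assemble the machine-readable summary; a pure function of stage outputs."""
    category_counts = classification["category"].value_counts().to_dict()
    n_retained = int(classification["retained"].sum())
    dropped = classification[~classification["retained"]]
    attrition = {
        "excluded_category": int(dropped["excluded_category"].sum()),
        "noncanonical_novel_junction": int(
            (~dropped["excluded_category"] & dropped["noncanonical_novel_junction"]).sum()),
        "rt_switch": int((~dropped["excluded_category"]
                          & ~dropped["noncanonical_novel_junction"]
                          & dropped["rt_switch"]).sum()),
        "end_support": int((~dropped["excluded_category"]
                            & ~dropped["noncanonical_novel_junction"]
                            & ~dropped["rt_switch"]).sum()),
    }
    multi = validation.dropna(subset=["validated"])
    validated_novel: dict[str, float] = {}
    for cl in sorted(set(cm_cl for s in spec.cluster_sets.values() for cm_cl in s)):
        novel_in_cl = [iso for iso, cs in spec.cluster_sets.items()
                       if cl in cs and categories.get(iso) in ("NIC", "NNC")]
        if novel_in_cl:
            ok = sum(bool(validation.loc[iso, "validated"]) is True
                     for iso in novel_in_cl if iso in multi.index)
            validated_novel[cl] = ok / len(novel_in_cl)
    specific = sum(1 for s in spec.cluster_sets.values() if len(s) == 1)
    upset = {"|".join(sorted(k)) if k else "(none)": v
             for k, v in sorted(spec.upset_tally.items(), key=lambda kv: sorted(kv[0]))}
    novel_hist = mtx.novel_per_gene_histogram(categories, gene_ids)
    return {
        "params": dataclasses.asdict(params),
        "reads": {
            "input": n_input_reads,
            "flnc": n_flnc,
            "rejected_by_reason": dict(sorted(reject_counts.items())),
            "alignment_rejects": dict(sorted(align_rejects.items())),
            "deduplicated_molecules": n_molecules,
        },
        "isoforms": {
            "total": int(len(classification)),
            "category_counts": dict(sorted(category_counts.items())),
            "retained": n_retained,
            "attrition": attrition,
        },
        "events": {t: {k: int(v) for k, v in row.items()}
                   for t, row in event_summary.iterrows()},
        "validation": {
            "junction_validated_isoforms": int((multi["validated"] == True).sum()),  # noqa: E712
            "multi_exon_isoforms": int(len(multi)),
            "per_cluster_novel_validation_rate": validated_novel,
        },
        "orfs": {
            "n_orfs": len(orfs),
            "orf_types": dict(sorted(pd.Series(
                [o.orf_type for o in orfs]).value_counts().to_dict().items())),
            "peptide_supported_isoforms": int(sum(supported.values())),
            "n_peptides": len(matches),
            "isoform_specific_peptides": int(sum(m.isoform_specific for m in matches)),
        },
        "specificity": {
            "detect_min": spec.detect_min,
            "cell_type_specific": specific,
            "total_isoforms": len(spec.cluster_sets),
            "upset": upset,
        },
        "matrix": {
            "total_umis": cell_matrix.total(),
            "n_isoforms": len(cell_matrix.isoform_ids),
            "n_cells": len(cell_matrix.barcodes),
        },
    }
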