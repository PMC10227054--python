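# Methods

This note documents the models, rules and numerical choices behind
`scisokit`, what the synthetic-data generator does and does not emulate, and
where the design was genuinely open.

## Coordinate and data model

All internal coordinates are 0-based half-open; GTF I/O converts to and from
the format's 1-based inclusive convention at the boundary, which confines
off-by-one reasoning to one module. Exon lists are stored in genomic order
regardless of strand; transcription order is derived on demand. A multi-exon
transcript's identity is its *junction chain* — the ordered list of
(donor, acceptor) genomic coordinates — and almost every downstream rule
(collapse, classification, event detection, deduplication) is a statement
about chains. On the minus strand the biological donor of a junction is the
genomic-right coordinate; all donor/acceptor logic is strand-aware.

## Demultiplexing

A full-length read is modelled as
`5'-primer | cDNA | polyA | UMI(12) | barcode(16) | 3'-primer`, sequenced in
either orientation. Extraction requires both primers (exact match first, then
a windowed scan allowing ≤ 2 mismatches), a polyA run of ≥ 20 nt adjacent to
the UMI/barcode block, and a whitelist barcode match. Barcode correction is
exact-or-unique-Hamming-1: substitution errors dominate in this read anatomy,
and indel-aware correction would buy nothing on the synthetic data while
complicating the uniqueness guarantee. The trailing-A run is stripped in
full, so genomically templated A's at the insert end are conservatively
counted as tail — this affects only the insert string used for dedup
tie-breaking, never the alignment-derived structure.

UMI deduplication keys on (barcode, UMI, junction chain) rather than the full
sequence: it is robust to 3′ length jitter, and the chain is the quantity the
catalog is built from. Mono-exonic reads, which have no chain, fall back to a
coarse (start, end) bin. The survivor of a duplicate group is the longest
insert, ties broken by read id, which makes the output order-independent.

## Collapse

Multi-exon reads merge on exact chain identity; transcript ends never
distinguish multi-exon isoforms, because 5′-truncated fragments are the job
of the ISM category and the end-support filter, not of collapse. Mono-exon
reads merge under reciprocal overlap with both end differences ≤ 100 nt. A
locus is a connected component of span overlap on one strand — this
reproduces per-gene-locus numbering without consulting the annotation — and
`PB.<locus>.<index>` ids are assigned by genomic order and descending read
support, making ids deterministic and permutation-invariant. The mapping
quality threshold defaults to 20 (configurable); the upstream convention is
only "low mapping quality", so the value is surfaced as a parameter.

## Classification and filtering

Gene assignment is maximal same-strand exonic overlap (≥ 1 nt). Multi-exon
logic is purely chain-based: equality → FSM; consecutive proper subchain →
ISM; otherwise NIC when every donor and acceptor is annotated for the gene,
NNC when not. With no same-strand exonic overlap the call degrades through
antisense (opposite-strand exonic overlap), fusion (junctions spanning ≥ 2
disjoint loci), genic_intron (wholly inside an intron), genic, intergenic.
Mono-exon queries are FSM against a mono-exon reference within a 100-nt end
fuzz (matching the collapse fuzz), ISM when contained in a reference exon,
genic otherwise.

Artifact filtering applies two junction tests to *novel* junctions only
(junctions absent from the assigned gene's annotated set):

* **Canonical motif** — the intron dinucleotides on the transcribed strand
  must be GT–AG, GC–AG or AT–AC, the spliceosomal motif set.
* **RT template switching** — reverse transcription can jump between direct
  repeats, fabricating junctions. The test is operationalized as an identical
  k-mer (k = 8, configurable) ending at the donor's exonic boundary and at
  the acceptor's intronic boundary. The upstream protocol names this test but
  never defines it; the direct-repeat form used here is the standard
  signature, and k = 8 makes chance hits (4⁻⁸ per junction) negligible at
  this scale.

End support requires the TSS within 50 nt of a CAGE peak **and** the TES
within 50 nt of a polyA peak (distance 0 inside a peak; boundary inclusive;
strand-aware, measured to the nearest covered base). The source rule's
AND/OR reading is ambiguous; AND is used because each peak type is only
evidence at its own end. The filter applies to ISM/NIC/NNC only — exact
annotation matches cannot be produced by genomic contamination or PCR
artifacts, so FSM is exempt — and both choices are configurable
(`categories_filtered`).

## Alternative-splicing events

Events are local (SUPPA-style), found pairwise over a gene's transcripts and
deduplicated by (type, coordinates); inclusion/exclusion transcript sets
accumulate across pairs. Definitions: ES — one transcript splices (d, a)
straight across an exon that the other carries flanked by junctions (d, es)
and (ee, a); RI — an exon spans another transcript's junction with both
flanking exon edges matching; MX — two non-overlapping exon alternatives
between a shared donor and acceptor; A5/A3 — junction pairs sharing one
boundary whose alternative exons *overlap* (alternative extension of the same
exon), typed on the transcribed strand (A5 = alternative donor); AF/AL —
the same shared-boundary pattern when the alternative exons are
*non-overlapping distinct first (last) exons*. The overlap criterion is what
separates A5/A3 from AF/AL; without it, a skipping pattern combined with a
shared acceptor would be double-typed. A5 and A3 are reported separately
even though one upstream flag covers both sites.

## ORFs and proteogenomics

ORF prediction is deliberately deterministic: the longest ATG-initiated
reading frame terminating at an in-frame stop within the mature transcript,
ties broken 5′-most, rejected below 100 codons. A statistical ORF caller
would add model-dependence without being oracle-testable; the preserved
constraint is the ≥ 100-codon threshold. A frame-preserving internal deletion
of 3k nt therefore shortens the protein by exactly k residues whenever the
ORF spans it and no new stop arises — the property the worked 63-nt/21-AA
example asserts.

ORF typing is strict: exact full-protein equality to a reference protein →
annotated; gene-assigned but different → variant; unassigned → novel-locus.
Peptide support is exact substring matching (no I/L folding, no PTMs) under
a standard tryptic digest (cleave after K/R, not before P, 0 missed
cleavages, length 7–40). A peptide is isoform-specific when it matches
exactly one predicted protein and is absent from the reference proteome —
the only peptide class that *proves* a novel isoform's translation.

## Validation, matrix, specificity

A junction validates when its short-read unique-read count is strictly
greater than 5 (≥ 6); an isoform validates when every junction does
(mono-exon isoforms are reported separately as not-applicable). The
isoform × cell matrix counts distinct UMIs per (isoform, barcode); the
min-cells = 3 / min-features = 50 filter exists only as an auxiliary view —
upstream it was a matrix-loading step for clustering, which this package
does not perform — and never touches the catalog. An isoform is detected in
a cluster when its summed count reaches `detect_min` (default 1; recorded in
the report since no detection threshold is stated upstream), and is
cell-type-specific when detected in exactly one cluster; the UpSet tally
partitions the isoform set by construction.

## The synthetic experiment

The generator states a small world and is deterministic under (config, seed):
20 non-overlapping genes on one contig, 1–3 reference transcripts per gene
(3–8 exons of 120–300 nt, introns 100–400 nt, all junctions GT–AG on the
transcribed strand), a planted long ORF per gene, novel isoforms as defined
perturbations (exon skip, donor/acceptor shift of 6–20 nt, alternative
first/last exon, retained intron, mutually exclusive exon, novel exon) whose
intended NIC/NNC label is derived from the splice sites they use; 4 clusters
of 50 cells at ~100 reads per cell (10x-V3-style 16-nt barcodes, 12-nt UMIs,
30-nt polyA tails); novel isoforms are cluster-exclusive with probability
0.7; 10 % PCR duplication, and optional 5′ truncation (default 5 %) and
single-substitution barcode errors (default 1 %). Junction support counts
are Poisson with mean 3× the number of spanning molecules, CAGE/polyA peaks
are 11-nt windows at the realized ends of expressed isoforms, and peptides
are tryptic samples from true ORFs plus length-matched shuffled decoys
screened against every ORF. Whitelist barcodes are generated at pairwise
Hamming distance ≥ 3 so every single error is uniquely correctable.

Three generator constraints are worth knowing. Retained-intron perturbations
are drawn only on interior junctions of hosts with ≥ 4 exons: retaining a
terminal intron leaves a chain that is a consecutive subchain of its host and
would be ISM by the chain-only category definitions, contradicting an
intended-novel label. Novel splice sites get canonical motifs patched into
the genome, so the default world is all-canonical and artifact flags fire
only on constructed inputs. And the manifest records *realized* expression
(clusters actually hit by ≥ 1 molecule), which is what noise-free recovery is
measured against.

What a green test on this world establishes: the pipeline's logic —
extraction, correction, dedup, collapse, chain classification, event
enumeration, ORF/peptide matching, conservation laws — is exact. What it
does not establish: robustness to alignment error, indels/chimeras, ambient
RNA, doublets, UMI collisions at depth, or any statistical property of real
cochlear data; the real catalog's headline counts arise from deep sequencing
that a desk-scale simulation cannot and does not try to reproduce.

## Determinism and degenerate inputs

All randomness flows from one seeded NumPy generator; orderings are
explicitly sorted, so identical configs produce byte-identical files (tested
at the pipeline level). Degenerate cases are defined rather than accidental:
empty reads reject as missing-5′-primer; mono-exon transcripts have empty
chains; genes with < 2 transcripts yield no events; transcripts with no
qualifying ORF simply lack one; unknown chromosomes classify as intergenic;
barcodes missing from the cluster table go to an explicit "unknown" cluster.
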