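"""ORF prediction, CDS grouping, ORF typing and proteogenomic peptide support.

The ORF caller is deterministic: the longest ATG-initiated reading frame that
terminates at an in-frame stop within the transcript, ties broken 5'-most,
rejected below ``min_codons`` (default 100, the catalog's coding threshold).
Peptide support is exact-substring matching of observed (tryptic) peptides
against predicted isoform proteins; a peptide is isoform-specific when it maps
to exactly one isoform and is absent from the reference proteome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}
_VALID_NT = re.compile(r"[ACGT]*\Z")
_VALID_AA = re.compile(r"[ACDEFGHIKLMNPQRSTVWY]+\Z")


@dataclass
class OrfRecord:
    isoform_id: str
    orf_start: int  # 0-based nt offset of the ATG in the transcript
    protein: str  # includes the initial M, excludes the stop
    orf_type: str | None = None  # annotated | variant | novel-locus


@dataclass
class PeptideMatch:
    peptide: str
    matched_isoform_ids: tuple[str, ...]
    in_reference_proteome: bool
    is_decoy_hit: bool = False

    @property
    def isoform_specific(self) -> bool:
        return len(self.matched_isoform_ids) == 1 and not self.in_reference_proteome


def predict_orf(seq: str, min_codons: int = 100, isoform_id: str = "") -> OrfRecord | None:
    """Longest ATG-initiated ORF with an in-frame stop; None below threshold."""
    seq = seq.upper()
    m = _VALID_NT.match(seq)
    if m is None:
        bad = next(i for i, c in enumerate(seq) if c not in "ACGT")
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    best: tuple[int, int] | None = None  # (protein_len, -start) maximized
    best_start = -1
    start = seq.find("ATG")
    while start != -1:
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos : pos + 3] in STOP_CODONS:
                n_aa = (pos - start) // 3
                if best is None or (n_aa, -start) > best:
                    best = (n_aa, -start)
                    best_start = start
                break
        start = seq.find("ATG", start + 1)
    if best is None or best[0] < min_codons:
        return None
    n_aa = best[0]
    protein = str(Seq(seq[best_start : best_start + 3 * n_aa]).translate())
    return OrfRecord(isoform_id, best_start, protein)


def unique_cds(orfs: Sequence[OrfRecord]) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Group isoforms by identical protein string.

    Returns (isoform_id -> group_id, group_id -> member isoform_ids); group
    ids are ``CDS.<n>`` numbered by first appearance in isoform-id order.
    """
    by_protein: dict[str, list[str]] = {}
    for orf in sorted(orfs, key=lambda o: o.isoform_id):
        by_protein.setdefault(orf.protein, []).append(orf.isoform_id)
    groups: dict[str, list[str]] = {}
    iso_to_group: dict[str, str] = {}
    for n, members in enumerate(sorted(by_protein.values(), key=lambda m: m[0]), start=1):
        gid = f"CDS.{n}"
        groups[gid] = members
        for iso in members:
            iso_to_group[iso] = gid
    return iso_to_group, groups


def classify_orf(
    orf: OrfRecord,
    gene_id: str | None,
    reference_proteome: Mapping[str, str],
) -> str:
    """Type an ORF against the reference proteome.

    Exact full-length protein match -> "annotated"; a gene-assigned isoform
    whose protein differs -> "variant"; no gene assignment -> "novel-locus".
    """
    if orf.protein in set(reference_proteome.values()):
        return "annotated"
    return "variant" if gene_id else "novel-locus"


def tryptic_peptides(
    protein: str, min_len: int = 7, max_len: int = 40, missed_cleavages: int = 0
) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P."""
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    fragments = [protein[a:b] for a, b in zip(cuts, cuts[1:])]
    peptides = []
    for i in range(len(fragments)):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            pep = "".join(fragments[i : j + 1])
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


def map_peptides(
    peptides: Iterable[str],
    orfs: Sequence[OrfRecord],
    reference_proteome: Mapping[str, str],
) -> tuple[list[PeptideMatch], dict[str, bool]]:
    """Match observed peptides to predicted isoform proteins by exact substring.

    Returns the per-peptide matches plus a per-isoform support flag (an
    isoform is supported when at least one peptide matches its protein).
    Decoy peptides simply match nothing.
    """
    ref_proteins = list(reference_proteome.values())
    matches: list[PeptideMatch] = []
    supported = {orf.isoform_id: False for orf in orfs}
    for pep in peptides:
        if not _VALID_AA.match(pep):
            raise ValueError(f"peptide {pep!r} contains non-amino-acid characters")
        hit_ids = tuple(sorted(o.isoform_id for o in orfs if pep in o.protein))
        in_ref = any(pep in p for p in ref_proteins)
        matches.append(PeptideMatch(pep, hit_ids, in_ref))
        for iso in hit_ids:
            supported[iso] = True
    return matches, supported
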