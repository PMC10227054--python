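"""Long-read demultiplexing: primer/polyA location, barcode correction, UMI dedup.

A full-length read is expected to look like (on one strand)

    5'-primer | insert | polyA | UMI | barcode | 3'-primer

and may be sequenced in either orientation. A read qualifies as FLNC
(full-length non-chimeric) only when both primers are found, the polyA run
adjacent to the UMI/barcode block is at least ``min_polya`` nucleotides
(default 20), and the barcode matches the whitelist exactly or at a unique
Hamming distance of 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from .annotation import revcomp

# Default primer pair used by the synthetic experiment generator. Deliberately
# share no long substring so orientation detection is unambiguous.
PRIMER_5P = "AAGCAGTGGTATCAACGCAGAGT"
PRIMER_3P = "CAGGACGATGTCTGAGCGAT"

REJECT_REASONS = (
    "no-5'-primer",
    "no-3'-primer",
    "no-polyA",
    "barcode-unmatched",
    "barcode-ambiguous",
)


@dataclass(frozen=True)
class FlncRecord:
    read_id: str
    barcode: str  # whitelist-corrected
    umi: str
    orientation: str  # "as-sequenced" | "reverse-complemented"
    insert: str
    polya_len: int


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def correct_barcode(observed: str, whitelist: Sequence[str] | frozenset[str]):
    """Whitelist barcode correction: exact, else unique Hamming-1 neighbor.

    Returns ``(barcode, None)`` on success or ``(None, reason)`` where reason
    is ``"unmatched"`` or ``"ambiguous"``.
    """
    wl = list(whitelist)
    if not wl:
        raise ValueError("whitelist is empty")
    bc_len = len(wl[0])
    if len(observed) != bc_len:
        return None, "unmatched"
    wl_set = set(wl)
    if observed in wl_set:
        return observed, None
    hits = [w for w in wl if _hamming(observed, w) == 1]
    if len(hits) == 1:
        return hits[0], None
    if len(hits) > 1:
        return None, "ambiguous"
    return None, "unmatched"


def _match_with_mismatches(seq: str, pattern: str, max_mm: int) -> bool:
    return len(seq) == len(pattern) and _hamming(seq, pattern) <= max_mm


def _find_primer_prefix(seq: str, primer: str, max_mm: int, search_window: int = 50) -> int:
    """Return the end offset of the 5' primer near the start of seq, or -1."""
    if seq.startswith(primer):
        return len(primer)
    n = len(primer)
    for off in range(0, max(1, min(search_window, len(seq) - n + 1))):
        if _match_with_mismatches(seq[off : off + n], primer, max_mm):
            return off + n
    return -1


def _find_primer_suffix(seq: str, primer: str, max_mm: int, search_window: int = 50) -> int:
    """Return the start offset of the 3' primer near the end of seq, or -1."""
    if seq.endswith(primer):
        return len(seq) - len(primer)
    n = len(primer)
    lo = max(0, len(seq) - n - search_window)
    for start in range(len(seq) - n, lo - 1, -1):
        if start >= 0 and _match_with_mismatches(seq[start : start + n], primer, max_mm):
            return start
    return -1


def extract_flnc(
    read_id: str,
    seq: str,
    whitelist: Sequence[str] | frozenset[str],
    primer_5p: str = PRIMER_5P,
    primer_3p: str = PRIMER_3P,
    min_polya: int = 20,
    barcode_len: int = 16,
    umi_len: int = 12,
    primer_mismatches: int = 2,
) -> FlncRecord | Rejection:
    """Reduce a raw long read to an FLNC record, or reject it with a reason.

    The read is tried as sequenced first, then reverse-complemented; extraction
    is invariant to reverse complementation up to the orientation flag.
    """
    seq = seq.upper()
    for orientation, s in (("as-sequenced", seq), ("reverse-complemented", revcomp(seq))):
        p5_end = _find_primer_prefix(s, primer_5p, primer_mismatches)
        if p5_end < 0:
            continue
        p3_start = _find_primer_suffix(s, primer_3p, primer_mismatches)
        if p3_start < 0 or p3_start <= p5_end:
            return Rejection(read_id, "no-3'-primer")
        body = s[p5_end:p3_start]
        if len(body) < barcode_len + umi_len + min_polya + 1:
            return Rejection(read_id, "no-polyA")
        barcode_obs = body[-barcode_len:]
        umi = body[-(barcode_len + umi_len) : -barcode_len]
        rest = body[: -(barcode_len + umi_len)]
        polya_len = len(rest) - len(rest.rstrip("A"))
        if polya_len < min_polya:
            return Rejection(read_id, "no-polyA")
        insert = rest[: len(rest) - polya_len]
        if not insert:
            return Rejection(read_id, "no-polyA")
        corrected, why = correct_barcode(barcode_obs, whitelist)
        if corrected is None:
            return Rejection(read_id, f"barcode-{why}")
        return FlncRecord(read_id, corrected, umi, orientation, insert, polya_len)
    return Rejection(read_id, "no-5'-primer")


def demux_reads(
    reads: Iterable[tuple[str, str]],
    whitelist: Sequence[str] | frozenset[str],
    **kwargs,
) -> tuple[list[FlncRecord], list[Rejection], Counter]:
    """Demultiplex (read_id, sequence) pairs; every read is exactly one of
    FLNC or rejected-with-reason."""
    wl = list(whitelist)
    flnc: list[FlncRecord] = []
    rejected: list[Rejection] = []
    reasons: Counter = Counter()
    for read_id, seq in reads:
        res = extract_flnc(read_id, seq, wl, **kwargs)
        if isinstance(res, FlncRecord):
            flnc.append(res)
        else:
            rejected.append(res)
            reasons[res.reason] += 1
    return flnc, rejected, reasons


def dedup_umis(
    records: Sequence[FlncRecord],
    chain_of: Mapping[str, Hashable],
) -> list[FlncRecord]:
    """Collapse records sharing (barcode, UMI, junction chain) to one molecule.

    ``chain_of`` maps read_id to a hashable chain key (from the aligned
    junction chain, or a gene assignment for mono-exonic reads). The survivor
    is the longest insert; ties break to the lexicographically smallest
    read_id. Records without a chain key are dropped (unaligned).
    """
    best: dict[tuple, FlncRecord] = {}
    for rec in records:
        if rec.read_id not in chain_of:
            continue
        key = (rec.barcode, rec.umi, chain_of[rec.read_id])
        cur = best.get(key)
        if cur is None or (-len(rec.insert), rec.read_id) < (-len(cur.insert), cur.read_id):
            best[key] = rec
    return sorted(best.values(), key=lambda r: r.read_id)
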