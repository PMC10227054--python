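"""Local alternative-splicing event detection among a gene's transcripts.

Seven event types are emitted, in the usual local-event (SUPPA-style)
vocabulary: ES (exon skipping), A5/A3 (alternative donor/acceptor, defined on
the transcribed strand), AF/AL (alternative first/last exon), RI (retained
intron) and MX (mutually exclusive exons). Events are found pairwise over a
gene's transcripts and deduplicated by (type, coordinates); participating
transcripts accumulate into inclusion/exclusion sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import TranscriptModel, junction_chain

EVENT_TYPES = ("ES", "A5", "A3", "AF", "AL", "RI", "MX")


@dataclass
class ASEvent:
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    inclusion: frozenset[str]
    exclusion: frozenset[str]

    def key(self) -> tuple:
        return (self.event_type, self.chrom, self.strand, self.coords)


def _pair_events(t1: TranscriptModel, t2: TranscriptModel) -> list[tuple[str, tuple, str, str]]:
    """Events between an unordered transcript pair.

    Returns (type, coords, inclusion_tid, exclusion_tid) tuples; for A5/A3/
    AF/AL the inclusion/exclusion split is by convention the transcript using
    the 5'-most alternative site.
    """
    out: list[tuple[str, tuple, str, str]] = []
    strand = t1.strand
    for a, b in ((t1, t2), (t2, t1)):
        ja = junction_chain(a).junctions
        jb = junction_chain(b).junctions
        a_j = set(ja)
        # ES: b splices (d, acc) straight across an exon (es, ee) of a that is
        # flanked in a by junctions (d, es) and (ee, acc)
        for d, acc in jb:
            for es, ee in ((e.start, e.end) for e in a.exons):
                if d < es and ee < acc and (d, es) in a_j and (ee, acc) in a_j:
                    out.append(("ES", (d, es, ee, acc), a.transcript_id, b.transcript_id))
        # RI: a has exon (s, e) spanning b's junction (d, acc) with both
        # flanking exon edges matching b's exons (s, d) and (acc, e)
        b_exons = {(e.start, e.end) for e in b.exons}
        for ex in a.exons:
            for d, acc in jb:
                if ex.start < d and acc < ex.end and (ex.start, d) in b_exons \
                        and (acc, ex.end) in b_exons:
                    out.append(("RI", (ex.start, d, acc, ex.end),
                                a.transcript_id, b.transcript_id))
        # MX: shared outer junction boundaries around two non-overlapping
        # alternative exons, one per transcript
        for i in range(len(ja) - 1):
            d1, s1 = ja[i]
            e1, a1 = ja[i + 1]
            for k in range(len(jb) - 1):
                d2, s2 = jb[k]
                e2, a2 = jb[k + 1]
                if d1 == d2 and a1 == a2 and (s1, e1) != (s2, e2) \
                        and (e1 <= s2 or e2 <= s1):
                    if s1 < s2:  # emit once per unordered exon pair
                        out.append(("MX", (d1, s1, e1, s2, e2, a1),
                                    a.transcript_id, b.transcript_id))
    # junction pairs sharing one boundary: A5/A3 vs AF/AL
    j1 = junction_chain(t1).junctions
    j2 = junction_chain(t2).junctions
    first1, last1 = (t1.exons[0], t1.exons[-1])
    first2, last2 = (t2.exons[0], t2.exons[-1])
    for L1, R1 in j1:
        for L2, R2 in j2:
            if R1 == R2 and L1 != L2:
                # alternative left boundary (genomic): the exons ending at L
                # must overlap (A5/A3); non-overlapping distinct first exons
                # spliced to the shared boundary are AF/AL instead
                ex1 = next(e for e in t1.exons if e.end == L1)
                ex2 = next(e for e in t2.exons if e.end == L2)
                if ex1.start < ex2.end and ex2.start < ex1.end:
                    etype = "A5" if strand == "+" else "A3"
                    coords = (min(L1, L2), max(L1, L2), R1)
                elif ex1 == first1 and ex2 == first2 \
                        and j1[0] == (L1, R1) and j2[0] == (L2, R2):
                    etype = "AF" if strand == "+" else "AL"
                    coords = (min(ex1.start, ex2.start), min(L1, L2),
                              max(ex1.start, ex2.start), max(L1, L2), R1)
                else:
                    continue
                inc, exc = (t1, t2) if L1 < L2 else (t2, t1)
                out.append((etype, coords, inc.transcript_id, exc.transcript_id))
            if L1 == L2 and R1 != R2:
                ex1 = next(e for e in t1.exons if e.start == R1)
                ex2 = next(e for e in t2.exons if e.start == R2)
                if ex1.start < ex2.end and ex2.start < ex1.end:
                    etype = "A3" if strand == "+" else "A5"
                    coords = (L1, min(R1, R2), max(R1, R2))
                elif ex1 == last1 and ex2 == last2 \
                        and j1[-1] == (L1, R1) and j2[-1] == (L2, R2):
                    etype = "AL" if strand == "+" else "AF"
                    coords = (L1, min(R1, R2), min(ex1.end, ex2.end),
                              max(R1, R2), max(ex1.end, ex2.end))
                else:
                    continue
                inc, exc = (t1, t2) if R1 < R2 else (t2, t1)
                out.append((etype, coords, inc.transcript_id, exc.transcript_id))
    return out


def detect_events(transcripts: Sequence[TranscriptModel]) -> list[ASEvent]:
    """Enumerate deduplicated local AS events among one gene's transcripts."""
    if len(transcripts) < 2:
        return []
    strand = transcripts[0].strand
    chrom = transcripts[0].chrom
    gene_id = transcripts[0].gene_id
    found: dict[tuple, tuple[set, set]] = {}
    ts = sorted(transcripts, key=lambda t: t.transcript_id)
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            for etype, coords, inc, exc in _pair_events(ts[i], ts[j]):
                key = (etype, coords)
                if key not in found:
                    found[key] = (set(), set())
                found[key][0].add(inc)
                found[key][1].add(exc)
    events = [
        ASEvent(etype, gene_id, chrom, strand, coords,
                frozenset(inc), frozenset(exc))
        for (etype, coords), (inc, exc) in found.items()
    ]
    events.sort(key=lambda e: (e.coords, e.event_type))
    return events


def summarize_events(
    events: Iterable[ASEvent],
    novelty: Mapping[str, str],
) -> pd.DataFrame:
    """Per-type event counts, split by whether any participant is novel.

    ``novelty`` maps every transcript id to "known" or "novel"; a missing
    transcript raises KeyError. Conservation holds by construction: the
    per-type totals sum to the number of events.
    """
    rows = {etype: {"total": 0, "novel": 0, "known_only": 0} for etype in EVENT_TYPES}
    for ev in events:
        participants = ev.inclusion | ev.exclusion
        for tid in participants:
            if tid not in novelty:
                raise KeyError(f"transcript {tid} missing from novelty map")
        any_novel = any(novelty[tid] == "novel" for tid in participants)
        rows[ev.event_type]["total"] += 1
        rows[ev.event_type]["novel" if any_novel else "known_only"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "event_type"
    return df
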