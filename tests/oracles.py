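"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the production code paths: classification is decided
by exhaustively testing every reference chain for equality/subchain and every
splice site for membership over naive per-base overlap sets; event
enumeration loops over transcript pairs with direct condition checks.
"""

from __future__ import annotations

from itertools import combinations

from scisokit.annotation import exons_from_chain, junction_chain


def _positions(exons) -> set[int]:
    out: set[int] = set()
    for e in exons:
        out.update(range(e.start, e.end))
    return out


def oracle_classify(chrom, strand, start, end, junctions, annotation, fuzz=100):
    """Naive SQANTI-style category decision by exhaustive enumeration."""
    if chrom not in {g.chrom for g in annotation.genes.values()}:
        return "intergenic"
    q_pos = _positions(exons_from_chain(chrom, start, end, junctions, strand))

    best_gene, best_ov = None, 0
    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        if g.chrom != chrom or g.strand != strand:
            continue
        ov = len(q_pos & _positions([e for t in g.transcripts for e in t.exons]))
        if ov > best_ov:
            best_gene, best_ov = g, ov
    if best_gene is not None:
        g = best_gene
        if junctions:
            ref_chains = [junction_chain(t).junctions for t in g.transcripts]
            if any(junctions == rc for rc in ref_chains):
                return "FSM"
            for rc in ref_chains:
                for i in range(len(rc)):
                    for j in range(i + 1, len(rc) + 1):
                        if rc[i:j] == junctions and len(junctions) < len(rc):
                            return "ISM"
            donors, acceptors = set(), set()
            for rc in ref_chains:
                for left, right in rc:
                    d, a = (left, right) if strand == "+" else (right, left)
                    donors.add(d)
                    acceptors.add(a)
            for left, right in junctions:
                d, a = (left, right) if strand == "+" else (right, left)
                if d not in donors or a not in acceptors:
                    return "NNC"
            return "NIC"
        # mono-exon
        for t in g.transcripts:
            if len(t.exons) == 1 and abs(t.start - start) <= fuzz and abs(t.end - end) <= fuzz:
                return "FSM"
        for t in g.transcripts:
            for e in t.exons:
                if e.start <= start and end <= e.end:
                    return "ISM"
        return "genic"

    other = "-" if strand == "+" else "+"
    for g in annotation.genes.values():
        if g.chrom == chrom and g.strand == other:
            if q_pos & _positions([e for t in g.transcripts for e in t.exons]):
                return "antisense"
    loci = [g for g in annotation.genes.values()
            if g.chrom == chrom and g.start < end and start < g.end]
    if junctions and len(loci) >= 2:
        spans = sorted((g.start, g.end) for g in loci)
        if all(a[1] <= b[0] for a, b in zip(spans, spans[1:])):
            return "fusion"
    for g in loci:
        for t in g.transcripts:
            for a, b in zip(t.exons, t.exons[1:]):
                if a.end <= start and end <= b.start:
                    return "genic_intron"
    return "genic" if loci else "intergenic"


def oracle_events(transcripts):
    """Exhaustive pairwise event enumeration; returns a set of (type, coords)."""
    found: set[tuple] = set()
    for t1, t2 in combinations(sorted(transcripts, key=lambda t: t.transcript_id), 2):
        strand = t1.strand
        for a, b in ((t1, t2), (t2, t1)):
            aj = set(junction_chain(a).junctions)
            bj = list(junction_chain(b).junctions)
            a_exons = [(e.start, e.end) for e in a.exons]
            b_exons = [(e.start, e.end) for e in b.exons]
            for d, acc in bj:
                for es, ee in a_exons:
                    if d < es and ee < acc and (d, es) in aj and (ee, acc) in aj:
                        found.add(("ES", (d, es, ee, acc)))
            for s, e in a_exons:
                for d, acc in bj:
                    if s < d and acc < e and (s, d) in b_exons and (acc, e) in b_exons:
                        found.add(("RI", (s, d, acc, e)))
            aj_list = list(junction_chain(a).junctions)
            for i in range(len(aj_list) - 1):
                d1, s1 = aj_list[i]
                e1, a1 = aj_list[i + 1]
                for k in range(len(bj) - 1):
                    d2, s2 = bj[k]
                    e2, a2 = bj[k + 1]
                    if d1 == d2 and a1 == a2 and (s1, e1) != (s2, e2) \
                            and (e1 <= s2 or e2 <= s1) and s1 < s2:
                        found.add(("MX", (d1, s1, e1, s2, e2, a1)))
        j1 = list(junction_chain(t1).junctions)
        j2 = list(junction_chain(t2).junctions)
        for L1, R1 in j1:
            for L2, R2 in j2:
                if R1 == R2 and L1 != L2:
                    ex1 = next(e for e in t1.exons if e.end == L1)
                    ex2 = next(e for e in t2.exons if e.end == L2)
                    overlap = ex1.start < ex2.end and ex2.start < ex1.end
                    if overlap:
                        found.add(("A5" if strand == "+" else "A3",
                                   (min(L1, L2), max(L1, L2), R1)))
                    elif ex1 is t1.exons[0] and ex2 is t2.exons[0] \
                            and j1[0] == (L1, R1) and j2[0] == (L2, R2):
                        found.add(("AF" if strand == "+" else "AL",
                                   (min(ex1.start, ex2.start), min(L1, L2),
                                    max(ex1.start, ex2.start), max(L1, L2), R1)))
                if L1 == L2 and R1 != R2:
                    ex1 = next(e for e in t1.exons if e.start == R1)
                    ex2 = next(e for e in t2.exons if e.start == R2)
                    overlap = ex1.start < ex2.end and ex2.start < ex1.end
                    if overlap:
                        found.add(("A3" if strand == "+" else "A5",
                                   (L1, min(R1, R2), max(R1, R2))))
                    elif ex1 is t1.exons[-1] and ex2 is t2.exons[-1] \
                            and j1[-1] == (L1, R1) and j2[-1] == (L2, R2):
                        found.add(("AL" if strand == "+" else "AF",
                                   (L1, min(R1, R2), min(ex1.end, ex2.end),
                                    max(R1, R2), max(ex1.end, ex2.end))))
    return found


def random_structural_queries(annotation, rng, n=500):
    """Randomized queries spanning FSM/ISM/NIC/NNC/antisense/intergenic shapes."""
    transcripts = list(annotation.transcripts())
    queries = []
    while len(queries) < n:
        t = transcripts[int(rng.integers(0, len(transcripts)))]
        chain = list(junction_chain(t).junctions)
        kind = rng.integers(0, 6)
        chrom, strand, start, end = t.chrom, t.strand, t.start, t.end
        if kind == 0:
            pass  # exact reference chain
        elif kind == 1 and len(chain) >= 2:  # consecutive subchain
            i = int(rng.integers(0, len(chain) - 1))
            j = int(rng.integers(i + 1, len(chain)))
            sub = chain[i:j]
            start, end = sub[0][0] - 50, sub[-1][1] + 50
            chain = sub
        elif kind == 2 and len(chain) >= 2:  # drop one junction (NIC-like)
            del chain[int(rng.integers(0, len(chain)))]
        elif kind == 3 and chain:  # shift a site (NNC-like)
            i = int(rng.integers(0, len(chain)))
            left, right = chain[i]
            chain[i] = (left + int(rng.integers(1, 5)), right)
        elif kind == 4:  # opposite strand
            strand = "-" if strand == "+" else "+"
        else:  # shifted far away, possibly mono-exon
            offset = int(rng.integers(50_000, 100_000))
            start, end = start + offset, end + offset
            chain = [(left + offset, right + offset) for left, right in chain]
        queries.append((chrom, strand, start, end, tuple(chain)))
    return queries


def oracle_orf(seq: str, min_codons: int):
    """Scan every ATG in every position; longest ORF with in-frame stop."""
    best = None  # (n_aa, -start)
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        pos = start + 3
        while pos + 3 <= len(seq):
            if seq[pos : pos + 3] in ("TAA", "TAG", "TGA"):
                n_aa = (pos - start) // 3
                cand = (n_aa, -start)
                if best is None or cand > best:
                    best = cand
                break
            pos += 3
    if best is None or best[0] < min_codons:
        return None
    return (-best[1], best[0])  # (orf_start, protein_length)
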