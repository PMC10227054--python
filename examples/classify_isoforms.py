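"""Structural classification of discovered isoforms against a reference.

Builds a two-transcript gene and classifies four query chains, illustrating
the FSM / ISM / NIC / NNC vocabulary.
"""

from scisokit import Annotation, GeneModel, GenomicInterval, TranscriptModel, classify


def transcript(tid, pairs, strand="+"):
    exons = [GenomicInterval("chr1", s, e, strand) for s, e in pairs]
    return TranscriptModel(tid, "Gjb6", strand, exons)


reference = Annotation([GeneModel("Gjb6", "+", [
    transcript("Gjb6-201", [(100, 200), (300, 400), (500, 600)]),
    transcript("Gjb6-202", [(100, 220), (500, 600)]),
])])

queries = {
    "exact chain of Gjb6-201": ((200, 300), (400, 500)),
    "3' fragment (suffix)": ((400, 500),),
    "known sites, new combination": ((200, 500),),
    "unannotated donor at 410": ((200, 300), (410, 500)),
}
for label, chain in queries.items():
    call = classify("chr1", "+", 150, 600, chain, reference)
    print(f"{label:32s} -> {call.category:4s} (gene {call.gene_id})")

# FSM/ISM chains match the annotation exactly or as a consecutive fragment;
# NIC recombines annotated splice sites into a new chain; NNC uses at least
# one splice site never seen in the annotation.
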