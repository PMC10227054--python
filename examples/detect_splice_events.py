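"""Local alternative-splicing events among a gene's transcripts.

Three small transcript pairs illustrate exon skipping (ES), an alternative
donor (A5) and a retained intron (RI).
"""

from scisokit import GenomicInterval, TranscriptModel, detect_events


def transcript(tid, pairs):
    return TranscriptModel(tid, "G", "+",
                           [GenomicInterval("chr1", s, e, "+") for s, e in pairs])


t1 = transcript("T1", [(0, 100), (200, 300), (400, 500)])
t2 = transcript("T2", [(0, 100), (400, 500)])        # skips the middle exon
t3 = transcript("T3", [(0, 120), (200, 300), (400, 500)])  # donor 100 -> 120
t4 = transcript("T4", [(0, 300), (400, 500)])        # retains the first intron

for ev in detect_events([t1, t2, t3, t4]):
    print(f"{ev.event_type}: coords={ev.coords} "
          f"inclusion={sorted(ev.inclusion)} exclusion={sorted(ev.exclusion)}")

# Each line is one deduplicated local event: the coordinates pin the
# alternative region and the inclusion/exclusion sets name the transcripts on
# either side of the choice.
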