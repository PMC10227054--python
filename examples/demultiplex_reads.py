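"""Demultiplexing one synthetic full-length read.

Shows the read anatomy (5' primer | cDNA | polyA | UMI | barcode | 3' primer),
whitelist barcode correction of a single sequencing error, and orientation
invariance.
"""

from scisokit import extract_flnc
from scisokit.annotation import revcomp
from scisokit.demux import PRIMER_3P, PRIMER_5P

whitelist = ["ACGTACGTACGTACGT", "TTTTCCCCGGGGAAAA"]
cdna = "TGCAGGCTTAGGCTAACGGATC"
umi = "AACCGGTTAACC"
barcode_with_error = "ACGTACGTACGTACGA"  # one substitution vs whitelist[0]

read = PRIMER_5P + cdna + "A" * 30 + umi + barcode_with_error + PRIMER_3P
for label, seq in (("as sequenced", read), ("reverse complemented", revcomp(read))):
    rec = extract_flnc("read1", seq, whitelist)
    print(f"{label:22s} barcode={rec.barcode} umi={rec.umi} "
          f"polyA={rec.polya_len} orientation={rec.orientation}")

# The erroneous barcode is corrected to its unique Hamming-distance-1
# whitelist neighbor, and both orientations yield the same record.
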