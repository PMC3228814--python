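"""Align a read against its Sanger reference and classify its errors.

Reproduces the classic homopolymer run-miscount: the reference carries a
2-G run (…AGGC…) and the read shows 3 Gs — "3G in place of 2" — which the
aligner must report as exactly one left-normalized G insertion.
"""

from pyroprof import ReferenceSequence, align_read, classify_read

REF = "CGGCTGATGGGGAGTCGACCAGGCTTAATATCTCCGAGGTTGCCCTCACAAATGGCGATG"
ref = ReferenceSequence(id="sanger", seq=REF, regions={"FR1": (0, 60)})
ref.validate()

read = REF.replace("AGGC", "AGGGC")  # one extra G inside the 2-G run
aln = align_read(read, ref)
print(f"alignment score {aln.score}, identity {aln.identity_pct:.1f}%, "
      f"reference span {aln.aligned_ref_span}")
for ev in aln.events:
    print(f"  event: {ev.type} {ev.read_bases!r} before position "
          f"{ev.ref_pos}, homopolymer {ev.hp_len} x {ev.hp_base}")

cls = classify_read(aln, ref)
print(f"category: {cls.category}  (frameshift={cls.frameshift}, "
      f"premature_stop={cls.premature_stop})")
print("one single-base insertion at the run's leftmost coordinate: the "
      "canonical call for a pyrosequencing run-length miscount, and a "
      "frameshift until corrected.")
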