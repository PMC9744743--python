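"""Scan a sequence for linear HS-binding motifs.

Heparan sulfate binds runs of basic residues (B = Arg/Lys/His) arranged in
characteristic patterns. Here we scan a short synthetic sequence and a
purification tag with the five stock patterns.
"""

import hsgraft as hg

seq = "AKKAKAGSGRKAKKGS"
hits = hg.scan_linear_motifs(seq)
print(f"sequence: {seq}")
for h in hits:
    print(
        f"  {h.pattern_id:8s} at {h.start}-{h.end}: {h.matched_subsequence}"
        f"  (basics at {', '.join(map(str, h.basic_positions))})"
    )
print(f"{len(hits)} motif hits — each is a candidate HS contact patch.")

tag = "WSHPQFEKGGGSGGGSGGSAWSHPQFEK"
print(f"\ntwin-strep tag: {len(hg.scan_linear_motifs(tag))} hits "
      "(its basics are never adjacent, so no motif forms)")
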