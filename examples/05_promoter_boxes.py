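"""Annotate core-promoter boxes relative to the TSS.

Uses the bundled Tal1-style fixture promoter, whose background is scrubbed
so the annotation is exact, plus the mutated CACCC-box control fragments.
"""

from promtarget import Motif, annotate_promoter, scan_motifs, tal1_like_promoter
from promtarget.simulate import TAL1_E3_RESTORED, TAL1_MUT_E3

seq, tss = tal1_like_promoter()
ann = annotate_promoter(seq, tss)
print(ann.to_string(index=False))
# Three CACCC boxes, two CCAAT boxes and a TATA box upstream of the TSS --
# the classical architecture of an erythroid RNA-polymerase-II promoter.

caccc = Motif("EKLF", "CACCC")
print(f"\nmutated E3 fragment CACCC hits: "
      f"{len(scan_motifs(TAL1_MUT_E3, [caccc]))} (box destroyed)")
print(f"restored E3 fragment CACCC hits: "
      f"{len(scan_motifs(TAL1_E3_RESTORED, [caccc]))} (box recovered)")
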