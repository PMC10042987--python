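"""Scanning intergenic gaps for long AT-rich insertions.

The rearranged preset plants pure-AT tracts of 205, 178 and 423 bp at three
junctions; the scan recovers them exactly and emits BED.
"""

import mitocomp as mc
from mitocomp.intergenic import insertions_bed

record, truth = mc.simulate_mitogenome(mc.conopomorpha_config(seed=1))

found = mc.detect_at_insertions(record, min_length=100, min_at=0.90)
print(f"{len(found)} AT-rich insertions detected "
      f"(planted: {len(truth.insertions)}):")
for ins in found:
    print(f"  {ins.left_gene} | {ins.right_gene}: {ins.length} bp, "
          f"AT fraction {ins.at_fraction:.2f}")

print("\nBED output (0-based half-open, score = 100 * AT fraction):")
print(insertions_bed(record, found), end="")
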