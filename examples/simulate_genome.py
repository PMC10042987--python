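"""Generating a synthetic annotated mitogenome with ground truth.

Writes GenBank + FASTA + a truth sidecar, then re-reads the GenBank file and
verifies the truth by recounting.
"""

import tempfile
from collections import Counter
from pathlib import Path

import mitocomp as mc
import mitocomp.codon_usage as cu

outdir = Path(tempfile.mkdtemp())
config = mc.ancestral_config(seed=42)
record, truth = mc.simulate_mitogenome(config)

mc.write_genbank(record, outdir / "sim.gb")
mc.write_fasta(record, outdir / "sim.fasta")
truth.write(outdir / "sim.truth.json")
print(f"wrote {record.length} bp genome to {outdir}/sim.gb")

back = mc.read_genbank(outdir / "sim.gb")
print(f"re-read: {len(back.features)} features "
      f"({len(back.features_by_category('PCG'))} PCGs, "
      f"{len(back.features_by_category('tRNA'))} tRNAs, "
      f"{len(back.features_by_category('rRNA'))} rRNAs + control region)")

# truth recount: codon tallies of an extracted gene match the sidecar exactly
gene = back.feature_by_name("COI")
counts = cu.count_codons([mc.extract_feature_sequence(back, gene)]).counts
assert counts == Counter(truth.codon_counts["COI"])
print("COI codon recount matches the truth sidecar exactly "
      f"({sum(counts.values())} codons)")
print("Same seed -> byte-identical genome; the sidecar makes every")
print("statistic in the package testable as parameter recovery.")
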