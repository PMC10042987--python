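# mitocomp

Comparative characterization of insect mitochondrial genomes, built for the
moth (Lepidoptera) regime: ~15–17 kb AT-rich circles carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and a control region.  The
package computes the standard descriptive statistics of a mitogenome
characterization study —
per-region base composition and strand skew, codon-usage bias, gene-order
rearrangement, AT-rich intergenic insertions — as a tested, reusable Python
library with a seeded synthetic-genome simulator providing ground truth.

## What it computes

**Composition and strand skew** per region (whole circle, PCGs, tRNAs,
rRNAs, control region):

    AT-skew = (A − T) / (A + T)        GC-skew = (G − C) / (G + C)

**Codon-usage bias** under a configurable genetic code (default: NCBI
translation table 5, the invertebrate mitochondrial code):

- RSCU — relative synonymous codon usage, `RSCU_i = k·n_i / Σ n_j` over a
  family of *k* synonymous codons; each family's values sum to *k*.
- ENC — Wright's effective number of codons, from per-family homozygosity
  `F = (n·Σp_i² − 1)/(n − 1)` averaged over synonymy classes; it ranges from
  20 (one codon per amino acid) to 62 (uniform usage, the code's synonymous
  capacity), lower = more biased.
- ENC-plot null curve `ENC* = 2 + s + 29/(s² + (1−s)²)` with `s = GC3`:
  genes far below the curve are biased beyond mutational GC pressure.
- PR2 bias: `x = G3/(G3+C3)` vs `y = A3/(A3+T3)`; (0.5, 0.5) is the
  no-strand-bias null.
- GC content by codon position (GC1/GC2/GC3) and a start/stop-codon census
  (ATN starts, CGA-started COI, truncated-T stops).

**Gene order** as a signed circular permutation: adjacency sets, breakpoint
distances, and rearrangement reports classifying swaps, translocations and
inversions with a minimal moved-gene certificate.

**Intergenic scan**: maximal annotation gaps around the circle, with
detection of long AT-rich insertions (default ≥ 100 bp at ≥ 90% AT) and BED
output.

**Simulator**: seeded, annotated circular genomes with configurable
composition targets, within-family codon weights, gene order and planted
AT-repeat tracts, plus a truth sidecar that recounts exactly.

## Worked example

```python
import mitocomp as mc

record, truth = mc.simulate_mitogenome(mc.conopomorpha_config(seed=1))
for row in mc.composition_table(record)[-2:]:
    print(row.region, row.length, round(row.pct_at, 2))
for ins in mc.detect_at_insertions(record):
    print(ins.left_gene, ins.right_gene, ins.length, ins.at_fraction)
```

prints

```
rRNAs 2098 85.22
D-loop 1389 95.61
trnR trnA 205 1.0
trnE trnF 178 1.0
trnS2 ND1 423 1.0
```

— the control region lands within sampling error of its 95.25% AT target,
and the three planted AT tracts (205/178/423 bp, the sizes reported for the
litchi fruit borer genome) are recovered at their exact lengths and
junctions.  Diffing this genome's gene order against the unrearranged
lepidopteran order flags the trnA/trnR swap with 2 breakpoints (see
`examples/gene_order_rearrangement.py`).

The `examples/` directory holds one short narrative script per capability;
`mitocomp --help` exposes the same pipeline as a command line
(`analyze`, `codon-usage`, `gene-order`, `insertions`, `simulate`).

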