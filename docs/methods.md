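# Methods

## Substrate and coordinates

The analysis substrate is an annotated circular genome: a nucleotide string
over {A,C,G,T,N} plus an ordered feature table.  Coordinates are 0-based
half-open internally (GenBank I/O converts to/from 1-based inclusive).  A
feature spanning the sequence origin is one object with `end > length`,
resolved modulo the genome length; this keeps every gene a single interval
and makes rotation of the sequence origin a no-op for all statistics.
Feature names are normalized through a curated synonym registry
(COI/COX1/"cytochrome c oxidase subunit I"; trnL(CUN)→trnL1; 12S
rRNA→rrnS; control region/A+T-rich region→D-loop, …).  Unrecognized names
are preserved with category `other` and excluded from category-based
statistics.  Leu/Ser tRNAs without an isoacceptor mark cannot be placed and
are treated as unresolved rather than guessed.

## Composition and skew

Percentages are taken over counted (non-N) bases; reported lengths include
N.  AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C) are scale-invariant, so
they give identical answers on counts and on percentages; a zero denominator
yields an undefined-skew signal (`None`), never a number.  Region rows
concatenate each gene's genome-forward slice (not the 5'→3' gene strand), so
the whole-genome row and the region rows share one fixed strand and are
mutually consistent; a `gene_strand` flag switches conventions.  Display
rounding is 2 dp, half away from zero; unrounded values are retained and
reported in full-precision columns.

One annotation discrepancy worth recording: the source characterization of
the litchi fruit borer genome gives the control region as 1,390 bp in prose
but 1,389 bp in its composition table, and its prose rRNA skews repeat the
tRNA row's values while the table's rRNA row (0.01/0.34) is the one
consistent with its own base percentages.  The package treats annotation
spans and the table as authoritative.

## Codon usage

The genetic code is a parameter (NCBI table id via Biopython); the default
is table 5 (invertebrate mitochondrial: AGA/AGG=Ser, AUA=Met, UGA=Trp),
whose family structure is twelve 2-fold, six 4-fold families, 6-fold Leu,
8-fold Ser, stops {UAA,UAG}.  Codons are counted in non-overlapping frame
from each CDS start; a trailing 1–2 nt remainder is a truncated stop
(completed to UAA by polyadenylation in vivo) and is tallied separately, as
are codons containing N.

- **RSCU** `= k·count/family total`; 0 for unused codons of a used family,
  absent for unused families.  Stop codons form their own 2-codon family so
  the usual "Ter" rows can be reported, but stops are excluded from ENC,
  GC1/2/3 and PR2.
- **Met start convention.** Published mitogenome codon tables sometimes fold
  initiation codons into a 4-codon Met family {AUA,AUG,AUU,CGA} (start
  codons translate as Met).  The default here is the standard table-5 Met
  family {AUA,AUG}; `rscu(..., met_start_compat=True)` reproduces the folded
  convention from a separately tallied start-codon count.
- **ENC** uses Wright's per-family homozygosity `F̂ = (nΣp² − 1)/(n − 1)`
  averaged within synonymy classes, `ENC = Σ_k n_aa(k)/F̄_k`, clamped to
  [20, 62].  Small-sample policy: families with n < 2 observed codons, or a
  non-positive F̂, are dropped from their class average; a wholly missing
  class is imputed as the mean of the available class averages.  Different
  published tools use different variants on tiny genes (reported mitogenome
  ENC minima below the 20-amino-acid floor imply one such variant); this
  implementation documents its own estimator and is verified against an
  independent brute-force recomputation rather than chasing any tool
  bit-for-bit.
- **GC3** is third-position GC over all non-stop codons (not
  synonymous-only GC3s); the two are rarely distinguished in mitogenome
  reports.  GC-overall is the pooled mean of GC1..GC3 over the same codon
  set, which makes the pooling identity exact.
- **PR2** pools third-position counts; an undefined axis (zero denominator)
  is signalled, not silently 0.

## Gene order

Orders are signed circular permutations, normalized by rotating to an
anchor gene with positive orientation (default trnM, adjacent to the
control region in moths; a negative anchor flips the circle).  Breakpoint
distance is the count of adjacencies of one order absent from the other;
unsigned adjacencies are the default because moth tRNA-cluster findings are
order-level, with a signed mode (junction canonicalized with its
opposite-strand reading) for inversion detection.  `diff_orders` also finds
a minimal set of genes whose removal makes the orders identical up to
rotation — exact subset search up to size 4, restricted (losslessly) to
genes incident to broken adjacencies, greedy beyond — and classifies the
difference: adjacent transposition → swap, relocation → translocation, sign
change → inversion.  Reconstruction of duplication/loss scenarios is out of
scope; the report describes observable differences only.

## Intergenic scan

Gaps are the maximal uncovered intervals between features around the circle
(the control region counts as a feature).  Detection flags gaps with width
≥ `min_length` (default 100) and AT fraction ≥ `min_at` (default 0.90) —
thresholds chosen so near-pure-AT tracts in the 150–450 bp range, the
reported insertion regime, all pass with margin; both are exposed on the
API and CLI.  Detection is region-level: no repeat-unit model is fitted,
since reported insertions are described only as AT-repeat tracts.

## Simulator

The simulator emits the study conditions rather than arbitrary data:

- **Plan.** 37 genes + control region in the lepidopteran (MIQ) order, gene
  sizes near reported moth values (PCGs sum to 11,209 bp ≈ the reported
  11,205; tRNAs 1,472; rRNAs 1,335 + 763; control 1,389), total ≈ 16.3 kb,
  inside the 15–17.1 kb regime of the compared species.  Strand assignment
  follows the moth genome (9 PCGs + 14 tRNAs majority strand; 4 PCGs,
  8 tRNAs, both rRNAs minority).  Truncated stops (length ≡ 1 mod 3) on
  COII, COIII, ND5 and CYTB.
- **Sequence model.** PCGs are built codon-by-codon so codon-bias statistics
  have exact ground truth: uniform amino-acid choice over the 20 families,
  within-family codon weights defaulting to the published litchi fruit
  borer usage (strongly A/U-ending), ATT/ATG starts with COI forced to CGA,
  UAA/UAG stops weighted by the published stop usage.  RNA genes, control
  region and spacers are i.i.d. draws from per-region base weights
  defaulting to the published per-region composition.  Uniform amino-acid
  composition is a deliberate simplification: it leaves within-family bias
  (what RSCU/ENC measure) faithful while making whole-PCG base content
  flatter than real genomes, so PCG-level AT% is not a calibration target.
- **Presets.** `ancestral_config` (unrearranged, 1–6 bp spacers) and
  `conopomorpha_config` (trnA/trnR swapped; pure-AT tracts of 205/178/423 bp
  planted at the trnR|trnA, trnE|trnF and trnS2|ND1 junctions, with zero
  spacers so each tract is exactly its gap and recovers at exact length).
  Planted tracts are TA-repeats mutated to G/C at rate 1 − at_fraction;
  the default at_fraction of 1.0 idealizes "almost completely AT" reported
  tracts and makes recovery deterministic.
- **Determinism and truth.** One integer seed feeds a single numpy
  Generator; the same config is byte-identical across platforms.  The truth
  sidecar stores the emitted gene order, per-gene codon tallies, planted
  insertions, target weights and a realized per-region composition recount;
  tests assert recount equality exactly and parameter recovery within 3σ
  binomial bounds.

What passing recovery tests show — and do not show — about real data: the
statistics are exact functions of annotated sequence, so correctness
transfers; but the simulator has no sequencing error, no annotation error,
no overlapping genes, no tRNA structure and no between-species divergence,
so robustness to those is untested by design.

## Problem sizes and tolerances

Tests run on full-size (~16–17 kb) simulated genomes — a single genome is
cheap — with a 13-genome batch exercising the multi-genome pipeline.
Stochastic recovery assertions use 3σ binomial bounds at the realized
region lengths (≈1,400–2,100 bp for the i.i.d. regions); exhaustive
breakpoint-oracle checks cover all circular orders of up to 8 genes.
Published-value regressions are exact at the printed 2-dp precision with
half-away-from-zero rounding.  Cross-species results that require the 12
comparator accessions (per-species ENC extremes, PR2 ranges) are not
reproduced; the screen arithmetic (17 of 169 genes above ENC 35 = 10.06%)
is verified as arithmetic.
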